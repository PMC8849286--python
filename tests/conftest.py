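import numpy as np
import pytest

from nkpatrol.track_analysis import Track


def make_track(positions, track_id="t0", cell_class="nk", dt=0.5, t0=0.0,
               censored=False):
    positions = np.asarray(positions, dtype=float)
    times = t0 + np.arange(len(positions)) * dt
    return Track(
        track_id=track_id,
        cell_class=cell_class,
        times=times,
        positions=positions,
        frame_interval=dt,
        censored=censored,
    )


def straight_track(speed_um_min, n_samples=10, dt=0.5, direction=(1.0, 0.0, 0.0),
                   origin=(0.0, 0.0, 0.0), **kwargs):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    steps = np.arange(n_samples)[:, None] * speed_um_min * dt * direction
    return make_track(np.asarray(origin) + steps, dt=dt, **kwargs)


def random_walk_tracks(rng, n_tracks, n_steps, step_sd=2.0, dt=0.5,
                       cell_class="nk", prefix="rw"):
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(0.0, step_sd, size=(n_steps, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        pos += rng.uniform(0, 100, size=3)
        tracks.append(
            make_track(pos, track_id=f"{prefix}_{i:03d}", cell_class=cell_class, dt=dt)
        )
    return tracks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
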