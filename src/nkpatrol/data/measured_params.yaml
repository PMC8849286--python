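# Default measured parameters for the NK lung-surveillance cascade.
# Keys carry explicit unit suffixes; values are converted to SI metres and
# minutes on load. Anatomy constants come from the mouse literature; the
# imaging-derived quantities are the intravital two-photon measurements.
blood_volume_m3: 1.7e-6
lung_volume_m3: 3.7e-7
cardiac_output_m3_per_min: 2.0e-5
total_capillary_length_m: 1.1e+3
fov_area_m2: 2.5e-7            # 0.5 mm x 0.5 mm field of view
platelet_speed_mm_per_s: 0.95  # capillary flow-speed proxy (= 0.057 m/min)
capillary_radius_um: 3.4
nk_diameter_um: 10.0           # also the effective imaging-slab thickness
nk_blood_conc_cells_per_m3: 5.1e+10
nk_per_fov_cells: 16
nk_crawl_speed_um_per_min: 4.8
observed_hit_rate_per_min: 8.0e-3
kill_probability: 0.5          # calcium-influx fraction of contacts
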