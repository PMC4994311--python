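# Final trigger thresholds (post-tuning): these are also the library defaults.
remaining_fraction_threshold: 0.50
min_ed_uc_visits: 2
ed_uc_window_days: 30
min_prescriptions: 3
rx_window_days: 30
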