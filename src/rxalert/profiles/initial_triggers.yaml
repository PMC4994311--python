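# Initial (pre-tuning, first silent-surveillance phase) trigger thresholds.
remaining_fraction_threshold: 0.30
min_ed_uc_visits: 3
ed_uc_window_days: 30
min_prescriptions: 3
rx_window_days: 30
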