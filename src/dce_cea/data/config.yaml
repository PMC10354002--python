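# Default run configuration. Exchange rate is the 2019 mid-year rate;
# afternoon_hours_fraction and room_share are calibrated once from the
# published per-category cost aggregates (see docs/methods.md).
exchange_rate: 14.0
afternoon_hours_fraction: 0.016
room_share: 0.015
ci_z: 1.959964
rounding: half_away_from_zero
sensitivity_bound: lower
floor_one: false
unrounded_effects: false
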