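# Reference calibration of the two-resource harvesting game.
# Individual optima: yellow 11 h on resource 1; red + blue 14 h combined
# (7 h each under an equal split) on the shared resource 2.
optimal_effort_r1: 11
optimal_effort_r2_total: 14
peak_individual_r1: 25
peak_total_r2: 50
width_r1: 11
width_r2: 14
coupling_strength: 0.5
max_hours: 20
n_rounds: 22
yield_form: parabola
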