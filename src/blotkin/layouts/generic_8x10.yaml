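# Generic 8x10 membrane with reference spots in all four corners.
# Unlisted spots are auto-named spot-r{row}c{col}; reference spots are "REF".
name: generic-8x10
n_rows: 8
n_cols: 10
spot_box: 30
reference_spots: [[0, 0], [0, 9], [7, 0], [7, 9]]
rotation_hint: 0
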