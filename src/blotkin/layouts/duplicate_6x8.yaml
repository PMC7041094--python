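# 6x8 membrane where every analyte is spotted in horizontal duplicate,
# the common format of commercial cytokine arrays.  Duplicate spots share a
# name and are averaged in reports.
name: duplicate-6x8
n_rows: 6
n_cols: 8
spot_box: 30
reference_spots: [[0, 0], [0, 7], [5, 0]]
rotation_hint: 0
analytes:
  - [0, 1, "POS"]
  - [0, 2, "POS"]
  - [0, 3, "NEG"]
  - [0, 4, "NEG"]
  - [0, 5, "IL-1b"]
  - [0, 6, "IL-1b"]
  - [1, 0, "IL-2"]
  - [1, 1, "IL-2"]
  - [1, 2, "IL-4"]
  - [1, 3, "IL-4"]
  - [1, 4, "IL-6"]
  - [1, 5, "IL-6"]
  - [1, 6, "IL-8"]
  - [1, 7, "IL-8"]
  - [2, 0, "IL-10"]
  - [2, 1, "IL-10"]
  - [2, 2, "IL-12"]
  - [2, 3, "IL-12"]
  - [2, 4, "IL-13"]
  - [2, 5, "IL-13"]
  - [2, 6, "IFN-g"]
  - [2, 7, "IFN-g"]
  - [3, 0, "TNF-a"]
  - [3, 1, "TNF-a"]
  - [3, 2, "GM-CSF"]
  - [3, 3, "GM-CSF"]
  - [3, 4, "MCP-1"]
  - [3, 5, "MCP-1"]
  - [3, 6, "MIP-1a"]
  - [3, 7, "MIP-1a"]
  - [4, 0, "RANTES"]
  - [4, 1, "RANTES"]
  - [4, 2, "VEGF"]
  - [4, 3, "VEGF"]
  - [4, 4, "EGF"]
  - [4, 5, "EGF"]
  - [4, 6, "FGF-2"]
  - [4, 7, "FGF-2"]
  - [5, 1, "PDGF-BB"]
  - [5, 2, "PDGF-BB"]
  - [5, 3, "TGF-b1"]
  - [5, 4, "TGF-b1"]
  - [5, 5, "BLANK"]
  - [5, 6, "BLANK"]
  - [5, 7, "BLANK"]
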