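# Conformational-metric comparisons among the deposited eIF2B entries.
#
# Frames: the "four C-terminal domains" alignment uses the β/δ C-terminal
# residue ranges below. The literature does not print exact domain
# boundaries, so these are calibration defaults (the β-alignment RMSD check
# in the companion targets file is the calibration control); override the
# ranges here if your entries differ.
#
# Role assignment for deposited entries: generate a reference library from
# the fully annotated complex entry (all ten eIF2B chains plus eIF2 α/γ).
data_dir: data/structures
fetch: [7D43, 7D44, 7D45, 7D46, 6CAJ, 6O81, 6O9Z]
reference_library: "entry:7D43"
comparisons:
  - id: apo_vs_alphaPgamma
    ref: 7D46
    target: 7D43
    kind: helix
    frame:
      - {role: eIF2B_beta, ranges: [[140, 345]]}
      - {role: eIF2B_delta, ranges: [[300, 520]]}
    probe: {role: eIF2B_delta, ranges: [[247, 267]]}
  - id: beta_alignment_apo_vs_alphaPgamma
    ref: 7D46
    target: 7D43
    kind: helix
    frame: {role: eIF2B_beta}
    probe: {role: eIF2B_delta, ranges: [[247, 267]]}
  - id: apo_vs_alphaP2
    ref: 7D46
    target: 7D44
    kind: helix
    frame:
      - {role: eIF2B_beta, ranges: [[140, 345]]}
      - {role: eIF2B_delta, ranges: [[300, 520]]}
    probe: {role: eIF2B_delta, ranges: [[247, 267]]}
  - id: apo_vs_alphaP1
    ref: 7D46
    target: 7D45
    kind: helix
    frame:
      - {role: eIF2B_beta, ranges: [[140, 345]]}
      - {role: eIF2B_delta, ranges: [[300, 520]]}
    probe: {role: eIF2B_delta, ranges: [[247, 267]]}
  - id: apo_vs_productive
    ref: 7D46
    target: 6O81
    kind: helix
    frame:
      - {role: eIF2B_beta, ranges: [[140, 345]]}
      - {role: eIF2B_delta, ranges: [[300, 520]]}
    probe: {role: eIF2B_delta, ranges: [[247, 267]]}
  - id: apo_vs_isolated_palpha
    ref: 7D46
    target: 6O9Z
    kind: helix
    frame:
      - {role: eIF2B_beta, ranges: [[140, 345]]}
      - {role: eIF2B_delta, ranges: [[300, 520]]}
    probe: {role: eIF2B_delta, ranges: [[247, 267]]}
  - id: pocket_alphaPgamma
    ref: 6CAJ
    target: 7D43
    kind: pocket
    shell: {shell: {ligand: ISRIB, radius: 10.0, reference: 6CAJ}}
  - id: pocket_alphaP1
    ref: 6CAJ
    target: 7D45
    kind: pocket
    shell: {shell: {ligand: ISRIB, radius: 10.0, reference: 6CAJ}}
  - id: pocket_isrib_alone
    ref: 6CAJ
    target: 7D46
    kind: pocket
    shell: {shell: {ligand: ISRIB, radius: 10.0, reference: 6CAJ}}
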