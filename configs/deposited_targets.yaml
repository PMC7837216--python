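# Published conformational metrics for the deposited-entry comparisons.
# Helix metrics may refer to either protomer copy (not stated which), so the
# per-protomer columns are listed and the closer one is compared; the same
# applies to the two alignment orientations of the pocket metric.
- id: helix_displacement_alphaPgamma
  comparison: apo_vs_alphaPgamma
  columns: [unit1_displacement_A, unit2_displacement_A]
  expected: 3.2
  tolerance: 0.3
- id: helix_rotation_alphaPgamma
  comparison: apo_vs_alphaPgamma
  columns: [unit1_rotation_deg, unit2_rotation_deg]
  expected: 7.9
  tolerance: 1.5
- id: beta_alignment_rmsd
  comparison: beta_alignment_apo_vs_alphaPgamma
  column: rmsd_fit_A
  expected: 0.7
  tolerance: 0.3
- id: helix_displacement_alphaP2
  comparison: apo_vs_alphaP2
  columns: [unit1_displacement_A, unit2_displacement_A]
  expected: 2.8
  tolerance: 0.3
- id: helix_rotation_alphaP2
  comparison: apo_vs_alphaP2
  columns: [unit1_rotation_deg, unit2_rotation_deg]
  expected: 8.1
  tolerance: 1.5
- id: helix_displacement_alphaP1
  comparison: apo_vs_alphaP1
  columns: [unit1_displacement_A, unit2_displacement_A]
  expected: 0.6
  tolerance: 0.3
- id: helix_displacement_productive
  comparison: apo_vs_productive
  columns: [unit1_displacement_A, unit2_displacement_A]
  expected: 1.1
  tolerance: 0.3
- id: helix_rotation_productive
  comparison: apo_vs_productive
  columns: [unit1_rotation_deg, unit2_rotation_deg]
  expected: 2.3
  tolerance: 1.5
- id: helix_displacement_isolated_palpha
  comparison: apo_vs_isolated_palpha
  columns: [unit1_displacement_A, unit2_displacement_A]
  expected: 2.4
  tolerance: 0.3
- id: pocket_shift_alphaPgamma
  comparison: pocket_alphaPgamma
  columns: [unit1_displacement_A, unit2_displacement_A]
  expected: 2.2
  tolerance: 0.3
- id: pocket_shift_alphaP1
  comparison: pocket_alphaP1
  columns: [unit1_displacement_A, unit2_displacement_A]
  expected: 0.4
  tolerance: 0.3
- id: pocket_shift_isrib_alone
  comparison: pocket_isrib_alone
  columns: [unit1_displacement_A, unit2_displacement_A]
  expected: 0.3
  tolerance: 0.3
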