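# Published reference values for the ATP.Mg2+ solution coordination
# equilibrium: uncorrected C3->C2 free-energy differences (kcal/mol) per
# force field, and the fitted sign-consistency offset intervals derived
# from a 30-complex protein:ATP test set (17 C3, 13 C2).
solution_dg_c3_to_c2:
  amber: 6.4
  charmm: -5.3
solution_dg_uncertainty:
  amber: 0.1
  charmm: 0.2
offset_interval:
  amber: [-7.1, -5.1]
  charmm: [2.5, 3.3]
test_set:
  n_complexes: 30
  n_c3: 17
  n_c2: 13
c2_distance_threshold_angstrom: 3.75
inaccessibility_cap_kcal_per_mol: 18.0
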