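# A small end-to-end run: 3 lobe clusters x 4 regions, 10+10 subjects.
simulation:
  seed: 7
  n_clusters: 3
  regions_per_cluster: 4
  n0: 10
  n1: 10
  T: 60
  rho_within: 0.5
  rho_between: 0.1
  effect_cluster_pair: Sub/Occ
  effect_size: 0.25
  fa_scale_group1: 0.85
  slab_thickness: 3
  covariates:
    - name: age
      kind: normal
      mean: 50.0
      sd: 6.0
      group_shift: 3.0
kinds: [DMC, DFA, fMT, fPC]
covariates: [age]
alpha: 0.05
missing_policy: exclude
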