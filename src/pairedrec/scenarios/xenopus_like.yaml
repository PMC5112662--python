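group1:
  n_genes: 20
  prefix: c1
  inhibitory: 5
  activating:
  - 6
group2:
  n_genes: 18
  prefix: c2
  inhibitory: 5
  activating:
  - 6
leader_codons: 20
n_codons: 107
igc_codons: 90
tm_codons: 40
cyt_codons: 32
cassette_offset: 4
intron_lengths:
- 250
- 300
- 280
- 220
spacer_mean: 700
spacer_jitter: 200
syn_rate: 0.0033
intron_rate_multiplier: 1.5
omega_background: 0.2
omega_selected: 2.0
kappa: 1.0
selected_windows:
  C:
  - 32
  - 41
  Cp:
  - 44
  - 52
  Cpp:
  - 55
  - 63
  F:
  - 78
  - 88
  G:
  - 91
  - 101
cherry_time: 200.0
dup_step: 8.0
subgroup_split_branch: 1.0
subgroup_split_omega: 0.8
speciation_time: 60.0
allotetraploid_time: 40.0
recent_duplications:
- gene: c206
  species: A
  time: 10.0
  suffix: x
conversions:
- donor: c105
  acceptor: c106
  species: A
  locus: ''
  tract:
  - 25
  - 103
  time: 5.0
- donor: c205
  acceptor: c206
  species: A
  locus: ''
  tract:
  - 25
  - 103
  time: 12.0
- donor: c205
  acceptor: c206x
  species: A
  locus: ''
  tract:
  - 25
  - 103
  time: 12.0
- donor: c105
  acceptor: c106
  species: B
  locus: L
  tract:
  - 25
  - 103
  time: 5.0
- donor: c205
  acceptor: c206
  species: B
  locus: L
  tract:
  - 25
  - 103
  time: 5.0
s_retained:
- c103
- c205
- c210
- c212
pseudogenes:
- gene: c108
  species: A
  locus: ''
  mechanism: internal_stop
- gene: c112
  species: A
  locus: ''
  mechanism: splice_donor
anchoring_overrides:
  c210: GPI
  c212: GPI
  c103: secreted
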