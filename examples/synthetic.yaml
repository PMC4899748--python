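# Default synthetic-plot run: 400 x 500 m, 500 quadrats, planted habitat
# filtering (high-WD species prefer convex ground, high-SLA species prefer
# fertile soil).
out_dir: out
plot_width: 400.0
plot_height: 500.0
quadrat_size: 20.0
variogram_family: spherical
fdis_standardize: zscore
carbon_fraction: 0.5
alpha: 0.05
seed: 1
simulate:
  n_species: 40
  beta_conv: {trait: wd, strength: 1.0}
  beta_soil: {trait: sla, strength: 1.0}
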