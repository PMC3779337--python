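# Recipe for the structure of the shipped 12-species community
# (allomweb synth --spec ... regenerates the structure; the shipped CSVs
# additionally condition observed densities on the reference equilibrium,
# see docs/methods.md).
n_producers: 6
n_invertebrates: 5
n_vertebrates: 1
producer_log10_mass: [-13.0, -12.0]
invertebrate_log10_mass: [-10.0, -8.0]
vertebrate_log10_mass: [-7.0, -6.0]
abundance_intercept: -2.0
abundance_slope: -0.8
abundance_scatter: 0.5
diet_window: [-6.0, -0.5]
target_links: 18
n_orphan_producers: 0
label: small-12
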