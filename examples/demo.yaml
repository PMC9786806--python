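# Demo configuration for `seedscreen all` / `seedscreen simulate`.
# A small mixed-cytotype population of apomictic triploids.
seed: 42
n_trees: 10
n_seeds_per_tree: 40
cytotype_proportions:
  3: 100
cv: 2.0
p_missing_endosperm: 0.02
p_multiple_endosperm: 0.005
sperm_set: [1, 1.5, 2, 2.5, 3, 4]
tolerance: 0.25
min_count: 4
k: 2
segments: 26
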