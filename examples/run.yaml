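# A full pipeline run on a simulated colony.
# Either give `simulate:` (truth overrides; omitted fields use the
# defaults) or `inputs:` with image_scores/sites/breeding CSV paths.
output_dir: out/run1
seed: 1
simulate:
  n_sites_per_subcolony: [27, 51]
  n_seasons: 3
presence_filters: [any, pair]
ci_method: wald
mcmc_fast: true   # 3 x 20,000 reduced schedule; false = 3 x 200,000
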