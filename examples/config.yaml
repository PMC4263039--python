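# Full-analysis run configuration.
# Unset file paths fall back to packaged fixtures (costs, risks,
# uncertainty parameters) or synthetic generation (mortality, population);
# every fallback is recorded in the summary's run log.
seed: 1
iterations: 1000
wtp_threshold: 62000     # ZAR per LYG; ~2012 GDP per capita (external assumption)
currency_rate: 8.21      # ZAR per USD, display only
national_strategy: per_band_delta_e
output_dir: capicea_output
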