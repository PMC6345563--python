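# Counts-only demo: reproduce the classification report from the
# packaged 2x2 counts (no images needed). Run from the repository root:
#   hcmito report --config examples/demo_pipeline.yaml
out_dir: results/demo
seed: 0
counts_path: examples/neomycin_counts.csv
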