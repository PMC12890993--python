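# Example experiment configuration for `partiquant run --config examples/experiment.yaml --out out/`
# Omitted keys fall back to the package defaults (all five conditions,
# reported recovery parameters, oracle segmentation).
slides_per_condition: 3
mpp: 2.0
slide_size_px: [512, 512]
segmentation: oracle   # or "learned" for the dual-learner path
min_overlap: 0.5
label_content_mg: 45.0
seed: 7
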