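# End-to-end model-membrane scenario: envelope of the 1 μm device,
# then a 30-replicate punctual-labeling diffusion ensemble.
name: slb-membrane
seed: 1
stages:
  - stage: envelope
    params: {device: device-1um, n_streamlines: 400}
  - stage: diffusion_ensemble
    params: {recipe: slb-gm1, replicates: 30}
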