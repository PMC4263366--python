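base_name,km_mM,ddg_bind_experiment,ddg_bind_poseA,ddg_bind_poseB
glucose,0.82,0.0,0.0,0.0
mannose,108,12.3,10.9,5.4
galactose,1.05,0.6,3.7,3.4
talose,79.1,11.5,5.6,3.6
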