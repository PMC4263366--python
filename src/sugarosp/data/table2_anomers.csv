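base_name,dg_beta_alpha_experiment,dg_beta_alpha_simulation
glucose,-1.2,-2.8
mannose,1.8,4.1
galactose,-1.7,-1.7
talose,1.0,3.0
allose,-4.1,-4.7
altrose,-1.1,-1.0
gulose,-4.8,-3.7
idose,-0.3,0.1
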