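surrogate,final,alpha,se_alpha,beta,se_beta,beta_S,se_beta_S,omega_SS,omega_FF
active T2 lesions,disability progression,-0.93,0.12,-0.37,0.19,-0.14,0.19,,
relapses,disability progression,-0.44,0.08,-0.37,0.19,-0.15,0.20,,
active T2 lesions,relapses,-0.90,0.13,-0.36,0.08,-0.17,0.09,,
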