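site,mechanism,dG_act,kappa,sigma,k_app
C23-H,FHT,6.0,2.1,1,4.10e8
C12,RAF,5.6,1.1,1,4.40e8
C13,RAF,8.3,1.1,1,5.60e6
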