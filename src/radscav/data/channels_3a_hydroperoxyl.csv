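site,mechanism,radical,dG_rxn,dG_act,kappa,sigma,nu_imag,v_forward,v_reverse
C23-H,FHT,HOO,9.6,,,3,,,
C24-H,FHT,HOO,14.8,,,3,,,
3a,SET,HOO,165.5,,,1,,,
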