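site,mechanism,radical,dG_rxn,dG_act,kappa,sigma,nu_imag,v_forward,v_reverse
C23-H,FHT,HO,-21.7,4.1,2.5,3,,,
C24-H,FHT,HO,-16.4,11.0,5.2,3,,,
C2,RAF,HO,-5.0,10.1,1.5,1,,,
C4,RAF,HO,4.2,13.4,1.4,1,,,
C5,RAF,HO,-19,7.2,1.2,1,,,
C6,RAF,HO,-9.3,7.6,1.2,1,,,
C7,RAF,HO,-10.9,7.3,1.2,1,,,
C8,RAF,HO,-15.5,6.5,1.2,1,,,
C9,RAF,HO,1.5,13.1,1.4,1,,,
C11,RAF,HO,-6.9,10.0,1.4,1,,,
C12,RAF,HO,-20.7,2.3,1.2,1,,,
C13,RAF,HO,-24.5,2.8,1.3,1,,,
C14,RAF,HO,-9.5,12.7,1.5,1,,,
C15,RAF,HO,-10.2,6.8,1.0,1,,,
C16,RAF,HO,-6.1,8.8,1.3,1,,,
C17,RAF,HO,-7.2,,,1,,,
C18,RAF,HO,-5.2,8.4,1.4,1,,,
C19,RAF,HO,-9.8,13.4,1.4,1,,,
C25,RAF,HO,-2.7,12.7,1.3,1,,,
C26,RAF,HO,-8.3,6.8,1.2,1,,,
C27,RAF,HO,-5.8,9.0,1.3,1,,,
C28,RAF,HO,-8.2,7.4,1.3,1,,,
C29,RAF,HO,-5.5,8.0,1.3,1,,,
C30,RAF,HO,-9.4,6.8,1.2,1,,,
N3,RAF,HO,13.8,,,1,,,
N10,RAF,HO,-2.5,10.3,1.7,1,,,
3a,SET,HO,155.6,,,1,,,
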