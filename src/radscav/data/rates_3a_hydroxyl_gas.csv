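site,mechanism,k
C23-H,FHT,4.94e10
C24-H,FHT,7.83e5
C2,RAF,3.67e5
C4,RAF,1.26e3
C5,RAF,3.98e7
C6,RAF,1.87e7
C7,RAF,3.31e7
C8,RAF,1.23e8
C9,RAF,2.35e3
C11,RAF,4.04e5
C12,RAF,1.45e11
C13,RAF,7.60e10
C14,RAF,4.52e3
C15,RAF,6.63e7
C16,RAF,3.13e6
C18,RAF,6.63e6
C19,RAF,1.14e3
C25,RAF,3.85e3
C26,RAF,7.95e7
C27,RAF,2.05e6
C28,RAF,3.01e7
C29,RAF,1.02e7
C30,RAF,7.95e7
N10,RAF,2.95e5
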