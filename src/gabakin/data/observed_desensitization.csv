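construct,tau_fast_s,tau_slow_s,pct_A_fast,pct_I_res,tau_w_s
CWT,4.8,24.4,33.3,10.0,18.0
C3,2.7,7.1,20.0,,6.2
C4,2.9,7.3,86.7,,3.4
C5,2.9,7.2,86.3,,3.3
C45,0.18,,98.8,0.8,
C345,0.07,,,,
C12345,0.04,,,,
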