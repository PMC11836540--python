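region,year,age_lo,asfr
default,2001,15,0.1
default,2001,20,0.17
default,2001,25,0.17
default,2001,30,0.12
default,2001,35,0.07
default,2001,40,0.03
default,2001,45,0.01
default,2100,15,0.02
default,2100,20,0.07
default,2100,25,0.1
default,2100,30,0.09
default,2100,35,0.05
default,2100,40,0.018
default,2100,45,0.004
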