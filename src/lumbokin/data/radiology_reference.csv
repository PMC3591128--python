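vertebra,movement,mean_deg,sd_deg
L1,FLX,33.94,4.91
L2,FLX,30.25,3.93
L3,FLX,24.78,6.20
L4,FLX,18.09,6.83
L5,FLX,9.69,4.50
L1,EXT,38.73,4.29
L2,EXT,34.17,4.29
L3,EXT,31.70,4.28
L4,EXT,24.25,5.24
L5,EXT,12.66,4.06
L1,LB,23.40,2.39
L2,LB,20.08,2.55
L3,LB,16.12,1.38
L4,LB,9.45,1.33
L5,LB,4.21,0.63
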