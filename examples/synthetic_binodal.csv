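peg_mw,po4_pct,peg_pct
300,5.0,19.51
300,7.5,14.78
300,10.0,11.19
300,12.5,8.48
300,15.0,6.42
300,17.5,4.86
300,20.0,3.68
600,5.0,16.07
600,7.5,12.17
600,10.0,9.22
600,12.5,6.98
600,15.0,5.29
600,17.5,4.01
600,20.0,3.03
1000,5.0,13.2
1000,7.5,10.0
1000,10.0,7.57
1000,12.5,5.74
1000,15.0,4.34
1000,17.5,3.29
1000,20.0,2.49
1500,5.0,10.9
1500,7.5,8.26
1500,10.0,6.25
1500,12.5,4.74
1500,15.0,3.59
1500,17.5,2.72
1500,20.0,2.06
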