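peg_mw,molar_fraction,et30
200,0.0,63.1
200,0.055,62.77
200,0.11,62.44
200,0.165,62.11
200,0.22,61.78
200,0.275,61.45
200,0.33,61.107
200,0.385,60.689
200,0.44,60.186
400,0.0,63.1
400,0.02625,62.706
400,0.0525,62.312
400,0.07875,61.919
400,0.105,61.525
400,0.13125,61.131
400,0.1575,60.734
400,0.18375,60.28
400,0.21,59.748
600,0.0,63.1
600,0.01975,62.59
600,0.0395,62.081
600,0.05925,61.571
600,0.079,61.062
600,0.09875,60.552
600,0.1185,60.0
600,0.13825,59.349
600,0.158,58.6
1000,0.0,63.1
1000,0.00975,62.603
1000,0.0195,62.106
1000,0.02925,61.608
1000,0.039,61.111
1000,0.04875,60.614
1000,0.0585,60.116
1000,0.06825,59.595
1000,0.078,59.009
1450,0.0,63.1
1450,0.00412,62.768
1450,0.00825,62.436
1450,0.01238,62.104
1450,0.0165,61.772
1450,0.02062,61.44
1450,0.02475,61.108
1450,0.02888,60.776
1450,0.033,60.444
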