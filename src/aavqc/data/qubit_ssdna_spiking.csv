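ds_ng_ul,ss_ng_ul,m1,m2
10,0,46.8,48.6
6.67,6.67,33.6,33.0
5,10,31.0,31.4
3.33,13.33,26.2,27.6
0,20,20.0,23.0
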