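force_pN,efficiency
0.0,0.299352
0.5,0.283248
1.0,0.263753
1.5,0.241735
2.0,0.218017
2.5,0.193374
3.0,0.168537
3.5,0.144191
4.0,0.120974
4.5,0.099477
5.0,0.080249
5.5,0.063789
6.0,0.050552
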