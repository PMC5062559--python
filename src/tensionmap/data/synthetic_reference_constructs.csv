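construct,ratio,efficiency
mTFP-5aa-mVenus,2.0,0.55
mTFP-TRAF-mVenus,1.0,0.11
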