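feature,value,unit
dp_AV,5.0,mmHg
dp_MV,2.38,mmHg
dp_PV,3.0,mmHg
dp_TV,47.0,mmHg
maxv_AV,1.15,m/s
maxv_MV,0.81,m/s
maxv_PV,0.814,m/s
maxv_TV,3.43,m/s
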