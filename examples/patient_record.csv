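key,value
lvedv,414
lvesv,274
hr,83
co,11.62
p_sys_cuff,97
p_dia_cuff,57
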