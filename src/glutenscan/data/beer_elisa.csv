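sample_id,gluten_mg_per_kg,label_group
C1,60.0,control
C2,146.3,control
C3,55.9,control
C4,9.0,control
C5,5.4,control
LG1,4.7,low_gluten
LG2,14.7,low_gluten
LG3,4.6,low_gluten
LG4,5.3,low_gluten
LG5,4.2,low_gluten
LG6,4.9,low_gluten
LG7,7.5,low_gluten
LG8,6.0,low_gluten
LG9,2.0,low_gluten
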