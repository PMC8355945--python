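name,length_m,rate_commute,rate_capture,speed_commute,speed_capture
greater_mouse_eared_bat,0.077,7,150,7,2
sperm_whale,16,2,50,2,4
harbor_porpoise,1.5,25,300,1,2
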