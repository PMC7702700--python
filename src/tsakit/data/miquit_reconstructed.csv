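label,order,events_exp,total_exp,events_ctl,total_ctl
feasibility,1,13,104,8,103
pilot,2,11,203,4,204
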