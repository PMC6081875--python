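patient_id,therapy,t_half_wb_h,t_half_spect_h
P1,octreotate,40,53
P2,octreotate,43,61
P3,octreotate,43,56
P4,octreotate,52,73
P5,octreotate,62,87
P6,psma617,22,33
P7,psma617,31,50
P8,psma617,65,67
P9,psma617,39,31
P10,psma617,29,42
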