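patient_id,therapy,d_total_rp_mgy_per_gbq,d_total_hp24_mgy_per_gbq,d_total_hp48_mgy_per_gbq,d_total_hp72_mgy_per_gbq
P1,octreotate,12.1,13.2,12.6,12.1
P2,octreotate,9.6,10.8,10.3,9.6
P3,octreotate,15.6,17.1,16.2,15.7
P4,octreotate,11.8,13.5,12.8,12.3
P5,octreotate,12.7,14.9,14.7,13.4
P6,psma617,10.2,11.3,9.6,10.1
P7,psma617,6.7,8.1,6.7,7.0
P8,psma617,16.8,17.1,17.1,16.8
P9,psma617,14.2,13.5,13.6,15.1
P10,psma617,8.3,10.0,8.1,8.5
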