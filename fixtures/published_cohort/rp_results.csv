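patient_id,therapy,d_total_mgy_per_gbq,pc_rob_percent,pc_blood_percent,pc_organs_percent
P1,octreotate,12.1,29,63,8
P2,octreotate,9.6,34,60,6
P3,octreotate,15.6,34,59,7
P4,octreotate,11.8,36,59,5
P5,octreotate,12.7,41,50,9
P6,psma617,10.2,36,56,8
P7,psma617,6.7,45,43,12
P8,psma617,16.8,80,13,7
P9,psma617,14.2,34,63,3
P10,psma617,8.3,60,28,12
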