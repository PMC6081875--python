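patient_id,therapy,sex,injected_activity_mbq,hct
P1,octreotate,male,7654,0.421
P2,octreotate,male,7425,0.442
P3,octreotate,female,7420,0.373
P4,octreotate,female,7409,0.341
P5,octreotate,female,7410,0.399
P6,psma617,male,3718,0.376
P7,psma617,male,3743,0.406
P8,psma617,male,3745,0.335
P9,psma617,male,3752,0.377
P10,psma617,male,3700,0.366
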