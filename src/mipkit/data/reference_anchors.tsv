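# anchor annotations for the packaged synthetic reference frames (1-based)
reference_id	anchor_name	position
synthAQP1_ref	arR_aromatic	56
synthAQP1_ref	arR_histidine	180
synthAQP1_ref	arR_cysteine	189
synthAQP1_ref	arR_arginine	195
synthAQP1_ref	P1	121
synthAQP1_ref	P2	199
synthAQP1_ref	P3	201
synthAQP1_ref	P4	241
synthAQP1_ref	P5	245
synthAQP1_ref	npa_b	76
synthAQP1_ref	npa_e	192
synthGLP_ref	arR_aromatic	56
synthGLP_ref	arR_histidine	180
synthGLP_ref	arR_cysteine	189
synthGLP_ref	arR_arginine	195
synthGLP_ref	P1	121
synthGLP_ref	P2	199
synthGLP_ref	P3	201
synthGLP_ref	P4	241
synthGLP_ref	P5	245
synthGLP_ref	npa_b	76
synthGLP_ref	npa_e	192
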