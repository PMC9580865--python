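surface_area_um2,blood_volume_um3,dlo2_ml_per_mmHg_min
207000,808000,295.616528926
121000,404000,86.4
121000,0,0
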