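produce,configuration,temperature_c,r_t_min_s_cm,r_t_max_s_cm,r_t_sd_s_cm,r_b_min_s_cm,r_b_max_s_cm,source
apple_jonagold,individual,20,391,391,67,4.8,4.8,measured
apple_jonagold,individual,1,750,750,96,5.2,5.2,measured
apple_jonagold,bulk,20,363,363,45,50.4,50.4,measured
strawberry,individual,,3,23,,,,literature
plum,individual,,23,38,,,,literature
radish_tuber,individual,,0.25,1.5,,1.0,1.5,literature
carrot,individual,,1,6,,1.2,2.4,literature
apple,individual,,170,320,,3.0,4.0,literature
white_asparagus,individual,,11,12.5,,1.0,2.0,literature
bell_pepper,individual,,35,80,,3.0,4.5,literature
radish_bunch,perforated_film,,,,,18.8,18.8,literature
radish_bunch,near_impermeable_film,,,,,820,820,literature
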