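id,group,rt_ms,accuracy_pct,p3_lat_ms,p3_amp_uv,erd_lat_ms,erd_amp_uv,map_p3,map_erd,edss,sdmt,pasat,bdi
HC1,healthy,408,,316,,460,,0.76,0.962,,,,
HC2,healthy,400,,322,,384,,0.967,0.945,,,,
HC3,healthy,594,,406,,486,,0.745,0.847,,,,
HC4,healthy,356,,396,,634,,0.762,0.834,,,,
HC5,healthy,377,,504,,432,,0.694,0.759,,,,
HC6,healthy,350,,366,,488,,0.835,0.925,,,,
HC7,healthy,396,,350,,436,,0.889,-0.048,,,,
HC8,healthy,400,,404,,464,,0.616,-0.386,,,,
HC9,healthy,485,,318,,306,,0.684,0.812,,,,
HC10,healthy,410,,330,,350,,0.682,0.925,,,,
LOW1,low-EDSS,501,,378,,676,,0.461,0.409,2,36,52,15
LOW2,low-EDSS,439,,410,,458,,0.876,0.077,2,76,54,6
LOW3,low-EDSS,414,,272,,406,,0.85,0.883,2,42,44,20
LOW4,low-EDSS,456,,374,,474,,0.438,-0.639,2,48,56,9
LOW5,low-EDSS,334,,348,,424,,0.865,0.871,1.5,45,43,8
LOW6,low-EDSS,463,,390,,508,,0.791,0.872,2,28,17,13
LOW7,low-EDSS,553,,334,,460,,0.755,0.398,2.5,39,47,20
LOW8,low-EDSS,553,,300,,446,,0.77,0.921,1,50,42,15
LOW9,low-EDSS,471,,422,,564,,0.413,0.235,2,53,51,14
LOW10,low-EDSS,386,,402,,572,,0.598,0.749,2,49,43,7
MOD1,moderate-EDSS,453,,316,,484,,0.469,0.437,4,50,45,10
MOD2,moderate-EDSS,560,,492,,570,,0.62,0.624,6,13,56,18
MOD3,moderate-EDSS,527,,596,,594,,0.299,0.821,6,20,52,3
MOD4,moderate-EDSS,467,,298,,534,,0.782,0.948,4,50,46,21
MOD5,moderate-EDSS,475,,590,,516,,0.867,0.727,5,32,22,16
MOD6,moderate-EDSS,631,,532,,540,,0.542,0.789,5.5,29,22,16
MOD7,moderate-EDSS,436,,360,,610,,0.56,0.872,5.5,32,41,30
MOD8,moderate-EDSS,398,,406,,634,,0.543,0.903,4,42,51,20
MOD9,moderate-EDSS,494,,558,,610,,0.243,0.94,6,20,42,20
MOD10,moderate-EDSS,498,,628,,584,,0.521,0.919,4,26,18,11
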