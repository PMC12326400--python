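therapy_id,brand,group,life_years,qalys,ace_eur_per_ly,acu_eur_per_qaly
apogo,Apo-Go,Apomorfina,6.385,2.885,12473,27615
dacepton,Dacepton,Apomorfina,6.385,2.885,9387,20782
percept_pc,Percept PC,DBS,6.495,2.800,10732,24874
percept_rc,Percept RC,DBS,6.495,2.800,13303,30833
duodopa,Duodopa,LCIG,7.055,3.120,30953,69909
foslevodopa,Foslevodopa,FosLD/FosCD SC,8.151,3.605,26808,60319
lecigon,Lecigon,LCEIG,7.055,3.120,46047,104000
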