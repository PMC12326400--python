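therapy_id,item_id,count
apogo,first_neuro_consult,1
apogo,neuro_review,9
apogo,apomorphine_test,1
apogo,lab_panel,1
dacepton,first_neuro_consult,1
dacepton,neuro_review,9
dacepton,apomorphine_test,1
dacepton,lab_panel,1
percept_pc,first_neuro_consult,1
percept_pc,neuro_review,7
percept_pc,first_neurosurgery_consult,1
percept_pc,neurosurgery_review,1
percept_pc,psychology_assessment,1
percept_pc,neurosurgery_admission,7
percept_pc,lab_panel,1
percept_pc,ekg,1
percept_pc,chest_xray,1
percept_pc,cranial_ct,1
percept_pc,cranial_mri,1
percept_pc,control_ct,1
percept_pc,control_mri,1
percept_pc,anesthesia_assessment,1
percept_pc,neurosurgery_procedure,1
percept_pc,dbs_implant_pc,1
percept_pc,dbs_replacement_pc,1
percept_rc,first_neuro_consult,1
percept_rc,neuro_review,7
percept_rc,first_neurosurgery_consult,1
percept_rc,neurosurgery_review,1
percept_rc,psychology_assessment,1
percept_rc,neurosurgery_admission,7
percept_rc,lab_panel,1
percept_rc,ekg,1
percept_rc,chest_xray,1
percept_rc,cranial_ct,1
percept_rc,cranial_mri,1
percept_rc,control_ct,1
percept_rc,control_mri,1
percept_rc,anesthesia_assessment,1
percept_rc,neurosurgery_procedure,1
percept_rc,dbs_implant_rc,1
percept_rc,dbs_replacement_rc,1
duodopa,first_neuro_consult,1
duodopa,neuro_review,7
duodopa,neurology_admission,1
duodopa,peg_procedure,1
duodopa,lab_panel,1
duodopa,abdominal_xray,1
foslevodopa,first_neuro_consult,1
foslevodopa,neuro_review,7
foslevodopa,lab_panel,1
lecigon,first_neuro_consult,1
lecigon,neuro_review,7
lecigon,neurology_admission,1
lecigon,peg_procedure,1
lecigon,lab_panel,1
lecigon,abdominal_xray,1
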