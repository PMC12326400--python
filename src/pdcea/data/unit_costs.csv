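item_id,label,unit_cost,source_year,phase
first_neuro_consult,Primera consulta neurologia,117.81,2023,pretreatment
neuro_review,Revision neurologia,58.90,2023,followup
first_neurosurgery_consult,Primera consulta neurocirugia,153.86,2023,pretreatment
neurosurgery_review,Revision neurocirugia,73.93,2023,followup
psychology_assessment,Valoracion psicologia,53.51,2023,pretreatment
neurology_admission,Ingreso neurologia,466.50,2023,procedure
apomorphine_test,Test apomorfina,147.66,2023,pretreatment
neurosurgery_admission,Ingreso neurocirugia,635.65,2023,procedure
peg_procedure,Gastrostomia endoscopica percutanea (PEG),4367.00,2023,procedure
lab_panel,Analitica,24.96,2023,pretreatment
ekg,Electrocardiograma,16.23,2023,pretreatment
chest_xray,Radiografia torax,9.23,2023,pretreatment
abdominal_xray,Radiografia abdomen,9.23,2023,pretreatment
cranial_ct,TAC craneo,55.38,2023,pretreatment
cranial_mri,RMN craneo,119.99,2023,pretreatment
control_ct,TAC control,55.38,2023,followup
control_mri,RMN control,119.99,2023,followup
anesthesia_assessment,Valoracion anestesia,89.74,2023,pretreatment
neurosurgery_procedure,Procedimiento quirurgico neurocirugia,23132.00,2023,procedure
dbs_implant_pc,DBS primer implante PC,24758.00,2023,procedure
dbs_replacement_pc,Recambio PC,16078.00,2023,followup
dbs_implant_rc,DBS primer implante RC,33110.00,2023,procedure
dbs_replacement_rc,Recambio RC,24430.00,2023,followup
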