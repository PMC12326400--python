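therapy_id,national_code,pack_price,dose_per_standard_unit,cost_per_standard_unit,standard_units_per_day,daily_dose_mg
apogo,74401,100.00,50,20,2,74.68
dacepton,79174,40.00,100,40,0.75,74.68
duodopa,66547,756.00,2000,108,1,1300
foslevodopa,88677,771.12,2400,110.16,1,1621
lecigon,86092,756.00,940,108,1.5,1164
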