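component,kind,key,lower,upper,points
smoking,category,never,,,100
smoking,category,current,,,0
smoking,band,quit_years,5,inf,75
smoking,band,quit_years,1,5,50
smoking,band,quit_years,0,1,25
bmi,band,bmi_kg_m2,0,25,100
bmi,band,bmi_kg_m2,25,30,70
bmi,band,bmi_kg_m2,30,35,30
bmi,band,bmi_kg_m2,35,40,15
bmi,band,bmi_kg_m2,40,inf,0
physical_activity,band,met_min_week,600,inf,100
physical_activity,band,met_min_week,480,600,90
physical_activity,band,met_min_week,360,480,80
physical_activity,band,met_min_week,240,360,60
physical_activity,band,met_min_week,120,240,40
physical_activity,band,met_min_week,4,120,20
physical_activity,band,met_min_week,0,4,0
sleep,band,sleep_hours,7,9,100
sleep,band,sleep_hours,9,10,90
sleep,band,sleep_hours,6,7,70
sleep,band,sleep_hours,5,6,40
sleep,band,sleep_hours,10,25,40
sleep,band,sleep_hours,4,5,20
sleep,band,sleep_hours,0,4,0
blood_pressure,band,sbp_mmHg,0,120,100
blood_pressure,band,sbp_mmHg,120,130,75
blood_pressure,band,sbp_mmHg,130,140,50
blood_pressure,band,sbp_mmHg,140,160,25
blood_pressure,band,sbp_mmHg,160,inf,0
blood_pressure,band,dbp_mmHg,0,80,100
blood_pressure,band,dbp_mmHg,80,90,50
blood_pressure,band,dbp_mmHg,90,100,25
blood_pressure,band,dbp_mmHg,100,inf,0
blood_pressure,deduction,treated,,,-20
non_hdl,band,non_hdl_mg_dl,0,130,100
non_hdl,band,non_hdl_mg_dl,130,160,60
non_hdl,band,non_hdl_mg_dl,160,190,40
non_hdl,band,non_hdl_mg_dl,190,220,20
non_hdl,band,non_hdl_mg_dl,220,inf,0
non_hdl,deduction,treated,,,-20
hba1c,band,hba1c_pct_no_diabetes,0,5.7,100
hba1c,band,hba1c_pct_no_diabetes,5.7,6.5,60
hba1c,band,hba1c_pct_diabetes,0,7,40
hba1c,band,hba1c_pct_diabetes,7,8,30
hba1c,band,hba1c_pct_diabetes,8,9,20
hba1c,band,hba1c_pct_diabetes,9,10,10
hba1c,band,hba1c_pct_diabetes,10,inf,0
diet,quartile_points,q1,,,0
diet,quartile_points,q2,,,33.333333333333336
diet,quartile_points,q3,,,66.66666666666667
diet,quartile_points,q4,,,100
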