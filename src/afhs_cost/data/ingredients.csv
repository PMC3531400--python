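intervention_id,item,category,quantity_per_case,unit_price,delivery_point
1a,information leaflet,medical_supply,1,0.10,any
1a,counseling contact,service_delivery,1,,any
1b,oral contraceptive cycles,drug,13,0.45,any
1b,provision visit,service_delivery,2,,any
1c,condoms,medical_supply,60,0.03,any
1c,distribution contact,service_delivery,1,,any
2a,iron-folate tablets,drug,180,0.01,any
2a,urine dipstick tests,lab_test,4,0.20,any
2a,antenatal visit,service_delivery,4,,any
2b,clean delivery kit,medical_supply,1,5.00,any
2b,oxytocin ampoule,drug,1,0.40,any
2b,delivery admission,service_delivery,1,,any
2c,micronutrient supplement,drug,1,0.50,any
2c,postnatal visit,service_delivery,2,,any
2d,ARV prophylaxis course,drug,1,8.00,any
2d,HIV rapid tests,lab_test,2,1.00,any
2d,PMTCT visit,service_delivery,4,,any
3,HIV rapid test,lab_test,1,1.00,any
3,counseling and testing visit,service_delivery,1,,any
4a,benzathine penicillin dose,drug,1,0.60,any
4a,RPR test,lab_test,1,0.50,any
4a,treatment visit,service_delivery,1,,any
4b,cefixime dose,drug,1,0.50,any
4b,treatment visit,service_delivery,1,,any
4c,azithromycin dose,drug,1,0.80,any
4c,treatment visit,service_delivery,1,,any
4d,antibiotic combination course,drug,1,3.50,any
4d,treatment visit,service_delivery,2,,any
5a,misoprostol course,drug,1,1.50,any
5a,aspiration kit share,medical_supply,1,2.00,any
5a,procedure visit,service_delivery,1,,any
5b,antibiotic course,drug,1,1.20,any
5b,follow-up visit,service_delivery,2,,any
6a,needles and syringes,medical_supply,200,0.08,any
6a,outreach contact,service_delivery,12,,any
6b,methadone daily doses,drug,365,0.30,any
6b,dispensing visit,service_delivery,52,,any
7,wound care supplies,medical_supply,1,2.50,any
7,emergency contraception,drug,1,0.80,any
7,injury care visit,service_delivery,2,,any
8a,cotrimoxazole daily doses,drug,365,0.02,any
8a,CD4 count tests,lab_test,2,8.00,any
8a,clinical review visit,service_delivery,4,,any
8b,first-line ARV regimen-year,drug,1,140.00,any
8b,monitoring tests,lab_test,2,8.00,any
8b,ART follow-up visit,service_delivery,6,,any
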