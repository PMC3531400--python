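activity_id,category,level,scaling_driver,item,quantity,unit_price
pm_national,management,national,per_country_year,coordination meetings,12,1500
pm_national,management,national,per_country_year,policy review and national AFHS standards,1,12000
pm_national,management,national,per_country_year,per diems and travel,40,150
tr_facility,training,facility,per_facility,trainee per diems,20,25
tr_facility,training,facility,per_facility,training materials,20,4
tr_facility,training,facility,per_facility,room rental,2,50
sv_district,supervision,district,per_district,supervision visits,12,90
sv_district,supervision,district,per_district,travel,12,40
iec_national,IEC,national,per_population,leaflets per 1000 adolescents,400,0.10
iec_national,IEC,national,per_population,posters per 1000 adolescents,6,4.00
iec_national,IEC,national,per_population,radio spots per 1000 adolescents,0.5,80
inf_facility,infrastructure_equipment,facility,per_facility,screen walls,1,250
inf_facility,infrastructure_equipment,facility,per_facility,secure cabinets,1,120
inf_facility,infrastructure_equipment,facility,per_facility,paint and decoration supplies,1,80
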