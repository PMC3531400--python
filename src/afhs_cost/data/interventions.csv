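intervention_id,name,group,package,need_basis,need_lo,need_hi,coverage_lo,coverage_hi,target_coverage,share_hospital,share_primary,share_community,sex_filter,requires_abortion_legal,requires_harm_reduction,costed_in
1a,Information on contraception,contraceptive_services,preventive_essential,sexually_active,0.19,0.99,0.02,0.30,0.95,0.0,0.90,0.10,both,False,False,main_model
1b,Contraceptive counseling and provision,contraceptive_services,preventive_essential,sexually_active,0.0,0.81,0.0,0.75,0.95,0.0,0.95,0.05,both,False,False,main_model
1c,Condom distribution,contraceptive_services,preventive_essential,sexually_active,0.0,0.81,0.0,0.69,0.95,0.0,0.50,0.50,both,False,False,main_model
2a,Basic antenatal care,maternity_care,preventive_essential,female_adolescents,0.03,0.29,0.0,0.988,0.95,0.90,0.05,0.05,female,False,False,maternity_model
2b,Care during childbirth,maternity_care,preventive_essential,female_adolescents,0.03,0.29,0.988,0.988,0.95,0.25,0.75,0.0,female,False,False,maternity_model
2c,Postpartum and postnatal care,maternity_care,preventive_essential,female_adolescents,0.03,0.29,0.988,0.988,0.95,0.0,0.60,0.40,female,False,False,maternity_model
2d,PMTCT,maternity_care,preventive_essential,female_adolescents,0.0,0.01,0.988,0.988,0.95,0.20,0.80,0.0,female,False,False,maternity_model
3,HIV testing and counseling,htc,preventive_essential,sexually_active,0.0,0.81,0.0,0.35,0.95,0.80,0.20,0.0,both,False,False,main_model
4a,Syphilis management,sti_management,curative_essential,condition_share,0.0,0.05,0.0,0.81,0.95,0.80,0.20,0.0,both,False,False,main_model
4b,Gonorrhoea management,sti_management,curative_essential,condition_share,0.0,0.08,0.0,0.81,0.95,0.80,0.20,0.0,both,False,False,main_model
4c,Chlamydia management,sti_management,curative_essential,condition_share,0.01,0.05,0.0,0.81,0.95,0.80,0.20,0.0,both,False,False,main_model
4d,PID management,sti_management,curative_essential,female_adolescents,0.02,0.04,0.0,0.81,0.95,0.80,0.20,0.0,female,False,False,main_model
5a,Safe abortion care,safe_abortion,curative_essential,female_adolescents,0.01,0.04,0.0,0.95,0.95,0.80,0.20,0.0,female,True,False,main_model
5b,Post-abortion care,safe_abortion,curative_essential,female_adolescents,0.01,0.04,0.0,0.75,0.95,0.20,0.80,0.0,female,False,False,main_model
6a,Needle and syringe exchange,harm_reduction,preventive_expanded,condition_share,0.0,0.01,0.0,0.81,0.95,0.0,0.30,0.70,both,False,True,main_model
6b,Opioid substitution therapy,harm_reduction,preventive_expanded,condition_share,0.0,0.005,0.0,0.67,0.50,0.0,1.0,0.0,both,False,True,main_model
7,Injury care due to IPV,ipv_injury_care,curative_expanded,female_adolescents,0.0,0.12,0.0,0.01,0.95,0.70,0.20,0.10,female,False,False,main_model
8a,"Care, support and treatment of opportunistic infections",hiv_care_treatment,curative_expanded,hiv_positive,0.0,0.03,0.0,0.58,0.95,0.20,0.80,0.0,both,False,False,main_model
8b,ART provision,hiv_care_treatment,curative_expanded,hiv_positive,0.0,0.01,0.17,0.83,0.95,0.85,0.15,0.0,both,False,False,main_model
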