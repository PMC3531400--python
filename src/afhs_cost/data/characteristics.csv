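number,dimension,text
1,equitable,Policies and procedures are in place that do not restrict the provision of health services on any terms
2,equitable,"Health care providers treat all adolescent clients with equal care and respect, regardless of status"
3,equitable,"Support staff treat all adolescent clients with equal care and respect, regardless of status"
4,accessible,Policies and procedures are in place that ensure that health services are either free or affordable to adolescents
5,accessible,The point of health service delivery has convenient hours of operation
6,accessible,Adolescents are well-informed about the range of available reproductive health services and how to obtain them
7,accessible,"Community members understand the benefits that adolescents will gain by obtaining the health services they need, and support their provision"
8,accessible,"Some health services and health-related commodities are provided to adolescents in the community by selected community members, outreach workers and adolescents themselves"
9,acceptable,Policies and procedures are in place that guarantee client confidentiality
10,acceptable,The point of health service delivery ensures privacy
11,acceptable,"Health-care providers are non-judgmental, considerate, and easy to relate to"
12,acceptable,"The point of health service delivery ensures consultations occur in a short waiting time, with or without an appointment, and (where necessary) swift referral"
13,acceptable,The point of health service delivery has an appealing and clean environment
14,acceptable,The point of health service delivery provides information and education through a variety of channels
15,acceptable,"Adolescents are actively involved in designing, assessing and providing health services"
16,appropriate,The required package of health care is provided to fulfill the needs of all adolescents either at the point of health service delivery or through referral linkages
17,effective,Health-care providers have the required competencies to work with adolescents and to provide them with the required health services
18,effective,Health-care providers use evidence-based protocols and guidelines to provide health services
19,effective,Health-care providers are able to dedicate sufficient time to work effectively with their adolescent clients
20,effective,"The point of health service delivery has the required equipment, supplies, and basic services necessary to deliver the required health services"
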