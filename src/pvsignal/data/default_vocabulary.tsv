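# Toy PT -> SOC vocabulary (two MedDRA-like levels only; no version claim).
# Sections: [pt_to_soc] with columns pt_code, pt_name, soc_name;
#           [synonyms] with columns canonical_name, variant.
[pt_to_soc]
pt_code	pt_name	soc_name
10000001	Nausea	Gastrointestinal disorders
10000002	Vomiting	Gastrointestinal disorders
10000003	Diarrhoea	Gastrointestinal disorders
10000004	Abdominal pain upper	Gastrointestinal disorders
10000005	Abdominal discomfort	Gastrointestinal disorders
10000006	Tooth discolouration	Gastrointestinal disorders
10000007	Dry mouth	Gastrointestinal disorders
10000008	Gastrointestinal disorder	Gastrointestinal disorders
10000009	Lip swelling	Gastrointestinal disorders
10000010	Tongue discolouration	Gastrointestinal disorders
10000011	Trichoglossia	Gastrointestinal disorders
10000012	Vomiting projectile	Gastrointestinal disorders
10000013	Tachycardia	Cardiac disorders
10000014	Eosinophilia	Blood and lymphatic system disorders
10000015	Pancytopenia	Blood and lymphatic system disorders
10000016	Internal haemorrhage	Vascular disorders
10000017	Drug ineffective for unapproved indication	General disorders and administration site conditions
10000018	Drug resistance	General disorders and administration site conditions
10000019	Unevaluable event	General disorders and administration site conditions
10000020	Disease progression	General disorders and administration site conditions
10000021	Peripheral swelling	General disorders and administration site conditions
10000022	Chest discomfort	General disorders and administration site conditions
10000023	Feeling hot	General disorders and administration site conditions
10000024	Infusion site phlebitis	General disorders and administration site conditions
10000025	Generalised oedema	General disorders and administration site conditions
10000026	Rash	Skin and subcutaneous tissue disorders
10000027	Rash pruritic	Skin and subcutaneous tissue disorders
10000028	Rash erythematous	Skin and subcutaneous tissue disorders
10000029	Skin discolouration	Skin and subcutaneous tissue disorders
10000030	Skin mass	Skin and subcutaneous tissue disorders
10000031	Rash papular	Skin and subcutaneous tissue disorders
10000032	Drug eruption	Skin and subcutaneous tissue disorders
10000033	Skin lesion	Skin and subcutaneous tissue disorders
10000034	Hypersensitivity	Immune system disorders
10000035	Poor quality sleep	Psychiatric disorders
10000036	Hypoaesthesia	Nervous system disorders
10000037	Intercostal neuralgia	Nervous system disorders
10000038	Restless legs syndrome	Nervous system disorders
10000039	Cough	Respiratory, thoracic and mediastinal disorders
10000040	Dysphonia	Respiratory, thoracic and mediastinal disorders
10000041	Hospitalisation	Surgical and medical procedures
10000042	Off label use	Injury, poisoning and procedural complications
10000043	Incorrect dose administered	Injury, poisoning and procedural complications
10000044	Incorrect product administration duration	Injury, poisoning and procedural complications
10000045	Drug dose titration not performed	Injury, poisoning and procedural complications
10000046	Wound secretion	Injury, poisoning and procedural complications
10000047	Procedural pain	Injury, poisoning and procedural complications
10000048	Hepatic enzyme increased	Investigations
10000049	Alanine aminotransferase increased	Investigations
10000050	Aspartate aminotransferase increased	Investigations
10000051	Weight decreased	Investigations
10000052	Blood pressure increased	Investigations
10000053	Blood alkaline phosphatase increased	Investigations
10000054	Blood bilirubin increased	Investigations
10000055	Infection	Infections and infestations
10000056	Pathogen resistance	Infections and infestations
10000057	Clostridium difficile infection	Infections and infestations
10000058	Clostridium difficile colitis	Infections and infestations
10000059	Cutaneous sporotrichosis	Infections and infestations
10000060	Lymphangitis	Infections and infestations
10000061	Mycobacterial infection	Infections and infestations
10000062	Osteomyelitis	Infections and infestations
10000063	Wound infection staphylococcal	Infections and infestations
10000064	Hepatic function abnormal	Hepatobiliary disorders
10000065	Hypoacusis	Ear and labyrinth disorders
10000066	Tinnitus	Ear and labyrinth disorders
10000067	Vision blurred	Eye disorders
10000068	Swelling of eyelid	Eye disorders
10000069	Eyelid rash	Eye disorders
[synonyms]
canonical_name	variant
omadacycline	omadacycline
omadacycline	nuzyra
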