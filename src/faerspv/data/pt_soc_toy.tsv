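# Toy MedDRA-style PT -> primary SOC dictionary (real MedDRA is licensed).
# PT names follow published anti-CGRP mAb safety reporting; SOC assignments
# are approximate and for testing/demo only.
Injection site pain	General disorders and administration site conditions
Injection site erythema	General disorders and administration site conditions
Injection site pruritus	General disorders and administration site conditions
Injection site haemorrhage	General disorders and administration site conditions
Injection site swelling	General disorders and administration site conditions
Injection site reaction	General disorders and administration site conditions
Injection site bruising	General disorders and administration site conditions
Injection site urticaria	General disorders and administration site conditions
Injection site rash	General disorders and administration site conditions
Injection site mass	General disorders and administration site conditions
Injection site extravasation	General disorders and administration site conditions
Injection site indentation	General disorders and administration site conditions
Injection site warmth	General disorders and administration site conditions
Infusion site pain	General disorders and administration site conditions
Infusion site bruising	General disorders and administration site conditions
Infusion related reaction	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Feeling abnormal	General disorders and administration site conditions
Chest discomfort	General disorders and administration site conditions
Influenza like illness	General disorders and administration site conditions
Drug ineffective	General disorders and administration site conditions
Constipation	Gastrointestinal disorders
Abdominal distension	Gastrointestinal disorders
Irritable bowel syndrome	Gastrointestinal disorders
Dry mouth	Gastrointestinal disorders
Swollen tongue	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Alopecia	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Rash	Skin and subcutaneous tissue disorders
Urticaria	Skin and subcutaneous tissue disorders
Erythema	Skin and subcutaneous tissue disorders
Trichorrhexis	Skin and subcutaneous tissue disorders
Anxiety	Psychiatric disorders
Insomnia	Psychiatric disorders
Depression	Psychiatric disorders
Panic attack	Psychiatric disorders
Abnormal dreams	Psychiatric disorders
Fear of injection	Psychiatric disorders
Hypoaesthesia	Nervous system disorders
Paraesthesia	Nervous system disorders
Paraesthesia oral	Nervous system disorders
Memory impairment	Nervous system disorders
Dizziness	Nervous system disorders
Migraine	Nervous system disorders
Migraine with aura	Nervous system disorders
Headache	Nervous system disorders
Muscle spasms	Musculoskeletal and connective tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
Arthralgia	Musculoskeletal and connective tissue disorders
Muscle tightness	Musculoskeletal and connective tissue disorders
Fibromyalgia	Musculoskeletal and connective tissue disorders
Throat irritation	Respiratory, thoracic and mediastinal disorders
Nasal congestion	Respiratory, thoracic and mediastinal disorders
Oropharyngeal pain	Respiratory, thoracic and mediastinal disorders
Throat tightness	Respiratory, thoracic and mediastinal disorders
Pharyngeal swelling	Respiratory, thoracic and mediastinal disorders
Palpitations	Cardiac disorders
Heart rate increased	Cardiac disorders
Raynaud's phenomenon	Vascular disorders
Flushing	Vascular disorders
Weight increased	Investigations
Hormone level abnormal	Investigations
Menstruation irregular	Reproductive system and breast disorders
Menstrual disorder	Reproductive system and breast disorders
Oligomenorrhoea	Reproductive system and breast disorders
COVID-19	Infections and infestations
Nasopharyngitis	Infections and infestations
Hypersensitivity	Immune system disorders
Anaphylactic reaction	Immune system disorders
Visual impairment	Eye disorders
Blepharospasm	Eye disorders
Concussion	Injury, poisoning and procedural complications
Off label use	Injury, poisoning and procedural complications
Medication error	Injury, poisoning and procedural complications
Accidental overdose	Injury, poisoning and procedural complications
Product quality issue	Product issues
Product dose omission issue	Product issues
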