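pt	soc
Myositis	Musculoskeletal and connective tissue disorders
Myocarditis	Cardiac disorders
Myasthenia gravis	Nervous system disorders
Febrile neutropenia	Blood and lymphatic system disorders
Pneumonitis	Respiratory, thoracic, and mediastinal disorders
Respiratory failure	Respiratory, thoracic, and mediastinal disorders
Pneumonia	Infections and infestations
Adverse event	General disorders and administration-site conditions
Transaminases increased	Investigations
Dyspnea	Respiratory, thoracic, and mediastinal disorders
Dyspnoea	Respiratory, thoracic, and mediastinal disorders
Malignant neoplasm progression	Neoplasms benign, malignant, and unspecified (including cysts and polyps)
Rash maculopapular	Skin and subcutaneous tissue disorders
Hepatitis	Hepatobiliary disorders
Cardiac failure	Cardiac disorders
Hypoxia	Respiratory, thoracic, and mediastinal disorders
Myelosuppression	Blood and lymphatic system disorders
Myasthenic syndrome	Nervous system disorders
Diplopia	Eye disorders
Septic shock	Infections and infestations
Fatigue	General disorders and administration-site conditions
Atrial fibrillation	Cardiac disorders
Cardiac arrest	Cardiac disorders
Pericardial effusion	Cardiac disorders
Pericarditis	Cardiac disorders
Tachycardia	Cardiac disorders
Bradycardia	Cardiac disorders
Cardiomyopathy	Cardiac disorders
Palpitations	Cardiac disorders
Myocardial infarction	Cardiac disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Colitis	Gastrointestinal disorders
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Pyrexia	General disorders and administration-site conditions
Asthenia	General disorders and administration-site conditions
Malaise	General disorders and administration-site conditions
Death	General disorders and administration-site conditions
Drug ineffective	General disorders and administration-site conditions
Product use issue	General disorders and administration-site conditions
Rash	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Alopecia	Skin and subcutaneous tissue disorders
Anaemia	Blood and lymphatic system disorders
Neutropenia	Blood and lymphatic system disorders
Thrombocytopenia	Blood and lymphatic system disorders
Hypothyroidism	Endocrine disorders
Hyperthyroidism	Endocrine disorders
Adrenal insufficiency	Endocrine disorders
Hypophysitis	Endocrine disorders
Arthralgia	Musculoskeletal and connective tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
Back pain	Musculoskeletal and connective tissue disorders
Renal failure	Renal and urinary disorders
Acute kidney injury	Renal and urinary disorders
Nephritis	Renal and urinary disorders
Hepatotoxicity	Hepatobiliary disorders
Hepatic function abnormal	Hepatobiliary disorders
Interstitial lung disease	Respiratory, thoracic, and mediastinal disorders
Cough	Respiratory, thoracic, and mediastinal disorders
Decreased appetite	Metabolism and nutrition disorders
Dehydration	Metabolism and nutrition disorders
Hyperglycaemia	Metabolism and nutrition disorders
Weight decreased	Investigations
Blood creatinine increased	Investigations
Alanine aminotransferase increased	Investigations
Aspartate aminotransferase increased	Investigations
Insomnia	Psychiatric disorders
Anxiety	Psychiatric disorders
Urinary tract infection	Infections and infestations
Sepsis	Infections and infestations
Oedema peripheral	General disorders and administration-site conditions
Chest pain	General disorders and administration-site conditions
Hypertension	Vascular disorders
Hypotension	Vascular disorders
Guillain-Barre syndrome	Nervous system disorders
Encephalitis	Nervous system disorders
Dermatitis bullous	Skin and subcutaneous tissue disorders
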