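# Synthetic PT -> primary SOC fixture map (NOT a MedDRA extract).
# Hand-assembled stand-in covering the synthetic vocabulary and test terms;
# real analyses require a user-supplied licensed MedDRA map.
# Columns: pt <TAB> soc <TAB> version
Bone giant cell tumor	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	synthetic-1
Bone giant cell tumor malignant	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Bone giant cell tumor benign	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to bone	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Breast cancer metastatic	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to liver	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to lung	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Prostate cancer metastatic	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to central nervous system	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to spine	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastasis	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to lymph nodes	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to pituitary gland	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to muscle	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastases to meninges	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Cancer of endometrium metastatic	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Cancer pain	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Osteosarcoma	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Malignant transformation	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Metastatic neoplasm	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Hormone-refractory prostate cancer	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Sarcoma	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Osteonecrosis of jaw	Musculoskeletal and connective tissue disorders
Exostosis of jaw	Musculoskeletal and connective tissue disorders
Bone pain	Musculoskeletal and connective tissue disorders
Pain in jaw	Musculoskeletal and connective tissue disorders
Osteonecrosis	Musculoskeletal and connective tissue disorders
Pathological fracture	Musculoskeletal and connective tissue disorders
Exposed bone in jaw	Musculoskeletal and connective tissue disorders
Bone disorder	Musculoskeletal and connective tissue disorders
Osteitis	Musculoskeletal and connective tissue disorders
Jaw disorder	Musculoskeletal and connective tissue disorders
Osteopetrosis	Musculoskeletal and connective tissue disorders
Bone lesion	Musculoskeletal and connective tissue disorders
Bone lesion excision	Musculoskeletal and connective tissue disorders
Jaw fistula	Musculoskeletal and connective tissue disorders
Osteolysis	Musculoskeletal and connective tissue disorders
Osteonecrosis of external auditory canal	Musculoskeletal and connective tissue disorders
Bone sequestrum	Musculoskeletal and connective tissue disorders
Hungry bone syndrome	Musculoskeletal and connective tissue disorders
Arthralgia	Musculoskeletal and connective tissue disorders
Back pain	Musculoskeletal and connective tissue disorders
Pain in extremity	Musculoskeletal and connective tissue disorders
Tooth disorder	Gastrointestinal disorders
Toothache	Gastrointestinal disorders
Tooth loss	Gastrointestinal disorders
Dental caries	Gastrointestinal disorders
Loose tooth	Gastrointestinal disorders
Gingival pain	Gastrointestinal disorders
Periodontal disease	Gastrointestinal disorders
Oral cavity fistula	Gastrointestinal disorders
Gingival disorder	Gastrointestinal disorders
Gingival recession	Gastrointestinal disorders
Tooth resorption	Gastrointestinal disorders
Pulpless tooth	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Diarrhea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Atypical femur fracture	Injury, poisoning and procedural complications
Femur fracture	Injury, poisoning and procedural complications
Tooth fracture	Injury, poisoning and procedural complications
Fracture	Injury, poisoning and procedural complications
Atypical fracture	Injury, poisoning and procedural complications
Spinal compression fracture	Injury, poisoning and procedural complications
Stress fracture	Injury, poisoning and procedural complications
Femoral neck fracture	Injury, poisoning and procedural complications
Jaw fracture	Injury, poisoning and procedural complications
Traumatic fracture	Injury, poisoning and procedural complications
Dental restoration failure	Injury, poisoning and procedural complications
Fall	Injury, poisoning and procedural complications
Off label use	Injury, poisoning and procedural complications
Product use in unapproved indication	Injury, poisoning and procedural complications
Osteomyelitis	Infections and infestations
Periodontitis	Infections and infestations
Tooth infection	Infections and infestations
Tooth abscess	Infections and infestations
Abscess jaw	Infections and infestations
Gingivitis	Infections and infestations
Gingival abscess	Infections and infestations
Dental fistula	Infections and infestations
Abscess oral	Infections and infestations
Abscess neck	Infections and infestations
Pneumonia	Infections and infestations
Periorbital abscess	Infections and infestations
Peri-implantitis	Infections and infestations
Blood calcium decreased	Investigations
Prostatic specific antigen increased	Investigations
Blood phosphorus decreased	Investigations
Blood parathyroid hormone increased	Investigations
Blood calcium abnormal	Investigations
Investigation	Investigations
Tumor marker increased	Investigations
Blood parathyroid hormone decreased	Investigations
Blood 1,25-dihydroxycholecalciferol increased	Investigations
Hypocalcemia	Metabolism and nutrition disorders
Hypercalcemia	Metabolism and nutrition disorders
Hypophosphatemia	Metabolism and nutrition disorders
Tetany	Metabolism and nutrition disorders
Hypomagnesaemia	Metabolism and nutrition disorders
Hypocalcemic seizure	Metabolism and nutrition disorders
Decreased appetite	Metabolism and nutrition disorders
Disease progression	General disorders and administration site conditions
Impaired healing	General disorders and administration site conditions
Therapy partial responder	General disorders and administration site conditions
Terminal state	General disorders and administration site conditions
Death	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Pain	General disorders and administration site conditions
Asthenia	General disorders and administration site conditions
Pyrexia	General disorders and administration site conditions
Malaise	General disorders and administration site conditions
Spinal cord compression	Nervous system disorders
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Gene mutation	Congenital, familial and genetic disorders
Hypercalcemia of malignancy	Endocrine disorders
Neutropenia	Blood and lymphatic system disorders
Anemia	Blood and lymphatic system disorders
Dyspnea	Respiratory, thoracic and mediastinal disorders
Tooth extraction	Surgical and medical procedures
Sequestrectomy	Surgical and medical procedures
Jaw operation	Surgical and medical procedures
Radiotherapy to bone	Surgical and medical procedures
Dental prosthesis user	Social circumstances
Economic problem	Social circumstances
Device breakage	Product issues
Rash	Skin and subcutaneous tissue disorders
Insomnia	Psychiatric disorders
Hypertension	Vascular disorders
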