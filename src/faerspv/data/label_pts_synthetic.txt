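# Synthetic product-label PT list (NOT extracted from actual prescribing
# information): the adverse events treated as "labeled" for the 120 mg
# oncology product in tests and synthetic runs.  One PT per line.
Bone giant cell tumor
Metastases to bone
Breast cancer metastatic
Metastases to liver
Metastases to lung
Prostate cancer metastatic
Metastases to central nervous system
Metastases to spine
Metastasis
Bone giant cell tumor malignant
Metastases to lymph nodes
Malignant transformation
Metastatic neoplasm
Sarcoma
Osteonecrosis of jaw
Bone pain
Pain in jaw
Osteonecrosis
Pathological fracture
Bone disorder
Osteitis
Jaw disorder
Osteonecrosis of external auditory canal
Tooth disorder
Toothache
Tooth loss
Dental caries
Loose tooth
Gingival pain
Periodontal disease
Gingival disorder
Atypical femur fracture
Femur fracture
Fracture
Atypical fracture
Spinal compression fracture
Femoral neck fracture
Jaw fracture
Osteomyelitis
Periodontitis
Tooth infection
Tooth abscess
Abscess jaw
Gingivitis
Gingival abscess
Abscess oral
Abscess neck
Blood calcium decreased
Blood phosphorus decreased
Blood calcium abnormal
Hypocalcemia
Hypercalcemia
Hypophosphatemia
Tetany
Hypomagnesaemia
Hypercalcemia of malignancy
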