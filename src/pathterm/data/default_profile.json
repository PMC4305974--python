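{
  "comment": "Default composition profile. The organ list, expansion multiplicities and value-set contents are a synthetic reconstruction of the interface-registry composition described in the literature the packaged equivalence table transcribes; they are NOT source content. Family structure: 9 core-generic elements, 28 staging/grading/classification, 15 marker, 1 procedure-row observation, 8 specific elements over 17 templates, 21 procedures.",
  "seed": 0,
  "oid_branch": "2.999.1.4",
  "organ_stride": 7,
  "organs": [
    "Breast", "Lung", "Colon", "Rectum", "Stomach", "Oesophagus", "Liver",
    "Pancreas", "Kidney", "Urinary bladder", "Prostate", "Testis", "Ovary",
    "Uterine cervix", "Endometrium", "Thyroid gland", "Skin", "Larynx",
    "Brain", "Lymph node"
  ],
  "problems": [
    {"token": "In situ neoplasm", "designation": "non-invasive tumor"},
    {"token": "Invasive neoplasm", "designation": "invasive tumor"}
  ],
  "families": {
    "core_generic": [
      {"element": "Lesion size, largest dimension", "contexts": 15, "value_set": []},
      {"element": "Specimen weight", "contexts": 15, "value_set": []},
      {"element": "Distance of lesion from closest uninvolved margin", "contexts": 15, "value_set": []},
      {"element": "Margins involvement", "contexts": 15, "value_set": ["Involved", "Not involved", "Cannot be assessed"]},
      {"element": "Number of lymph nodes involved", "contexts": 15, "value_set": []},
      {"element": "Lesion focality", "contexts": 15, "value_set": ["Unifocal", "Multifocal"]},
      {"element": "Macroscopic type", "contexts": 15, "value_set": ["Expansile", "Infiltrative", "Mixed"]},
      {"element": "Treatment effect", "contexts": 15, "value_set": ["No response", "Partial response", "Complete response"]},
      {"element": "Extent", "contexts": 15, "value_set": ["Confined to organ", "Beyond organ", "Adjacent structures"]}
    ],
    "staging_grading_classification": [
      {"element": "pT", "contexts": 8, "value_set": ["pTX", "pT0", "pTis", "pT1", "pT2", "pT3", "pT4"]},
      {"element": "pN", "contexts": 8, "value_set": ["pNX", "pN0", "pN1", "pN2", "pN3"]},
      {"element": "pM", "contexts": 8, "value_set": ["pM0", "pM1"]},
      {"element": "ypT", "contexts": 8, "value_set": ["ypTX", "ypT0", "ypT1", "ypT2", "ypT3", "ypT4"]},
      {"element": "ypN", "contexts": 8, "value_set": ["ypNX", "ypN0", "ypN1", "ypN2", "ypN3"]},
      {"element": "ypM", "contexts": 8, "value_set": ["ypM0", "ypM1"]},
      {"element": "UICC stage", "contexts": 8, "value_set": ["Stage 0", "Stage I", "Stage II", "Stage III", "Stage IV"]},
      {"element": "FIGO stage", "contexts": 8, "value_set": ["IA", "IB", "II", "III", "IV"]},
      {"element": "Ann Arbor stage", "contexts": 8, "value_set": ["I", "II", "III", "IV"]},
      {"element": "Pathologic stage group", "contexts": 8, "value_set": ["0", "I", "II", "III", "IV"]},
      {"element": "Clinical stage", "contexts": 8, "value_set": ["Early", "Locally advanced", "Metastatic"]},
      {"element": "Dukes stage", "contexts": 8, "value_set": ["A", "B", "C", "D"]},
      {"element": "Histological grade", "contexts": 8, "value_set": ["G1", "G2", "G3"]},
      {"element": "Nuclear grade", "contexts": 8, "value_set": ["Grade 1", "Grade 2", "Grade 3"]},
      {"element": "Nottingham score", "contexts": 8, "value_set": ["3", "4", "5", "6", "7", "8", "9"]},
      {"element": "Gleason score", "contexts": 8, "value_set": ["6", "7", "8", "9", "10"]},
      {"element": "Fuhrman grade", "contexts": 8, "value_set": ["1", "2", "3", "4"]},
      {"element": "WHO grade", "contexts": 8, "value_set": ["I", "II", "III", "IV"]},
      {"element": "Mitotic score", "contexts": 8, "value_set": ["1", "2", "3"]},
      {"element": "Tubule formation score", "contexts": 8, "value_set": ["1", "2", "3"]},
      {"element": "Cytological type", "contexts": 8, "value_set": ["Type A", "Type B", "Type C"]},
      {"element": "Histological type", "contexts": 8, "value_set": ["Type 1", "Type 2", "Type 3"]},
      {"element": "ICD-O classification", "contexts": 8, "value_set": ["8000/0", "8000/3", "8010/3"]},
      {"element": "WHO classification", "contexts": 8, "value_set": ["Class I", "Class II", "Class III"]},
      {"element": "Bethesda category", "contexts": 8, "value_set": ["I", "II", "III", "IV", "V", "VI"]},
      {"element": "Lauren classification", "contexts": 8, "value_set": ["Intestinal", "Diffuse", "Mixed"]},
      {"element": "Vienna classification", "contexts": 8, "value_set": ["1", "2", "3", "4", "5"]},
      {"element": "Banff classification", "contexts": 8, "value_set": ["1", "2", "3", "4", "5", "6"]}
    ],
    "marker": [
      {"element": "Estrogen receptor", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "Progesterone receptor", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "Androgen receptor", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "HER2 expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "Ki-67 expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "p53 expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "CD117 expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "S100 expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "Chromogranin expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "Synaptophysin expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "PD-L1 expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "ALK expression", "contexts": 6, "value_set": ["Positive", "Negative", "Equivocal"]},
      {"element": "KRAS mutation", "contexts": 6, "value_set": ["Detected", "Not detected"]},
      {"element": "BRAF mutation", "contexts": 6, "value_set": ["Detected", "Not detected"]},
      {"element": "EGFR mutation", "contexts": 6, "value_set": ["Detected", "Not detected"]}
    ],
    "procedure_observation": [
      {"element": "Lymph node sampling", "contexts": 1, "value_set": ["Performed", "Not performed"]}
    ],
    "specific": [
      {"element": "Breslow thickness", "contexts": 2, "value_set": ["Present", "Absent"]},
      {"element": "Mitotic activity impression", "contexts": 2, "value_set": ["Present", "Absent"]},
      {"element": "Hormonal milieu assessment", "contexts": 2, "value_set": ["Present", "Absent"]},
      {"element": "Crypt architecture distortion", "contexts": 2, "value_set": ["Present", "Absent"]},
      {"element": "Villous atrophy severity", "contexts": 2, "value_set": ["Present", "Absent"]},
      {"element": "Transformation zone appearance", "contexts": 2, "value_set": ["Present", "Absent"]},
      {"element": "Capsular penetration depth", "contexts": 2, "value_set": ["Present", "Absent"]},
      {"element": "Serosal reaction character", "contexts": 3, "value_set": ["Present", "Absent"]}
    ],
    "procedures": [
      "Specimen photography", "Frozen section examination", "Gross dissection",
      "Paraffin embedding", "Haematoxylin and eosin staining",
      "Immunohistochemical staining", "Histochemical staining",
      "Decalcification", "Tissue fixation", "Specimen radiography",
      "Image acquisition", "Image annotation", "Whole slide scanning",
      "Macro photography documentation", "Specimen accessioning",
      "Block selection", "Recut preparation", "Deeper levels preparation",
      "Cytospin preparation", "Smear preparation", "Cell block preparation"
    ]
  }
}
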