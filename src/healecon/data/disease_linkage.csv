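disease,weight,activity,fruit,vegetable
Diabetes,1,1,1,0
Hypertensive heart disease,1,0,0,0
Asthma,1,0,0,0
Ischemic heart disease,1,1,1,1
Ischemic stroke,1,1,1,1
Hemorrhagic stroke,1,0,1,1
Chronic kidney disease,1,0,0,0
Leukemia,1,0,0,0
Osteoarthritis,1,0,0,0
Gout,1,0,0,0
Low back pain,1,0,0,0
Cataract,1,0,0,0
Gallbladder and biliary diseases,1,0,0,0
Atrial fibrillation and flutter,1,0,0,0
Alzheimer's disease and other dementias,1,0,0,0
Breast cancer,1,1,0,0
Colon and rectum cancer,1,1,0,0
Esophageal cancer,1,0,1,0
Gallbladder and biliary tract cancer,1,0,0,0
Kidney cancer,1,0,0,0
Larynx cancer,0,0,1,0
Lip and oral cavity cancer,0,0,1,0
Liver cancer,1,0,0,0
Multiple myeloma,1,0,0,0
Nasopharynx cancer,0,0,1,0
Other pharynx cancer,0,0,1,0
Non-Hodgkin's lymphoma,1,0,0,0
Ovarian cancer,1,0,0,0
Pancreatic cancer,1,0,0,0
Thyroid cancer,1,0,0,0
Tracheal bronchus and lung cancer,0,0,1,0
Uterine cancer,1,0,0,0
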