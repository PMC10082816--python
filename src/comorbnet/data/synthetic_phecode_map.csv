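code_system,icd_code,phecode,phenotype,category
ICD10CM,A00.0,900.0,Essential hypertension,circulatory system
ICD9CM,100.0,900.0,Essential hypertension,circulatory system
ICD10CM,B00.1,900.1,Hyperlipidemia,endocrine/metabolic
ICD9CM,101.1,900.1,Hyperlipidemia,endocrine/metabolic
ICD10CM,C00.2,900.2,Type 2 diabetes,endocrine/metabolic
ICD9CM,102.2,900.2,Type 2 diabetes,endocrine/metabolic
ICD10CM,D00.3,900.3,Major depressive disorder,mental disorders
ICD9CM,103.3,900.3,Major depressive disorder,mental disorders
ICD10CM,E00.4,900.4,Anxiety disorder,mental disorders
ICD9CM,104.4,900.4,Anxiety disorder,mental disorders
ICD10CM,F00.5,900.5,Urinary tract infection,genitourinary
ICD9CM,105.5,900.5,Urinary tract infection,genitourinary
ICD10CM,G00.6,900.6,Memory loss,neurological
ICD9CM,106.6,900.6,Memory loss,neurological
ICD10CM,H00.7,900.7,Vascular dementia,mental disorders
ICD9CM,107.7,900.7,Vascular dementia,mental disorders
ICD10CM,I00.8,900.8,Psychosis,mental disorders
ICD9CM,108.8,900.8,Psychosis,mental disorders
ICD10CM,J00.9,900.9,Cerebrovascular disease,circulatory system
ICD9CM,109.9,900.9,Cerebrovascular disease,circulatory system
ICD10CM,K00.0,901.0,Osteoporosis,musculoskeletal
ICD9CM,110.0,901.0,Osteoporosis,musculoskeletal
ICD10CM,L00.1,901.1,Osteoarthrosis,musculoskeletal
ICD9CM,111.1,901.1,Osteoarthrosis,musculoskeletal
ICD10CM,M00.2,901.2,Pain in joint,symptoms
ICD9CM,112.2,901.2,Pain in joint,symptoms
ICD10CM,N00.3,901.3,Malaise and fatigue,symptoms
ICD9CM,113.3,901.3,Malaise and fatigue,symptoms
ICD10CM,R00.4,901.4,Other anemias,hematopoietic
ICD9CM,114.4,901.4,Other anemias,hematopoietic
ICD10CM,A01.5,901.5,Atrial fibrillation,circulatory system
ICD9CM,115.5,901.5,Atrial fibrillation,circulatory system
ICD10CM,B01.6,901.6,Gastroesophageal reflux disease,digestive
ICD9CM,116.6,901.6,Gastroesophageal reflux disease,digestive
ICD10CM,C01.7,901.7,Acute renal failure,genitourinary
ICD9CM,117.7,901.7,Acute renal failure,genitourinary
ICD10CM,D01.8,901.8,Acquired hypothyroidism,endocrine/metabolic
ICD9CM,118.8,901.8,Acquired hypothyroidism,endocrine/metabolic
ICD10CM,E01.9,901.9,Bipolar,mental disorders
ICD9CM,119.9,901.9,Bipolar,mental disorders
ICD10CM,F01.0,902.0,Other upper respiratory disease,respiratory
ICD9CM,120.0,902.0,Other upper respiratory disease,respiratory
ICD10CM,G01.1,902.1,Inflammation of eyelids,sense organs
ICD9CM,121.1,902.1,Inflammation of eyelids,sense organs
ICD10CM,H01.2,902.2,Tinnitus,sense organs
ICD9CM,122.2,902.2,Tinnitus,sense organs
ICD10CM,G30.1,290.11,Alzheimer's disease,mental disorders
ICD10CM,G30.8,290.11,Alzheimer's disease,mental disorders
ICD10CM,G30.9,290.11,Alzheimer's disease,mental disorders
ICD10CM,Z99.9,999.9,Synthetic uncategorized condition,
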