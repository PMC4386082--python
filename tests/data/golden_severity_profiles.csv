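phenotype_code,n_patients,prevalence,treatment_time,n_comorbidities,n_medications,n_procedures,cost
CHRONIC1,1,0.25,0.0,0.0,0.0,1.0,0.0
MILD1,2,0.5,1.0,0.5,1.5,2.0,67.5
SEVERE1,2,0.5,5.0,0.5,1.0,1.5,60.0
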