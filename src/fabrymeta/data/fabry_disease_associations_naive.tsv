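disease_name	genes
Malignant neoplasm of breast	AGT,ALB,APOA1,APOA4,CLU,GC,GRN,IGK,ITIH4,PSAP,PTGDS,RNASE1,SERPINA3,SLURP1,TF,YWHAZ
Breast carcinoma	AGT,ALB,APOA1,APOA4,CLU,GC,GRN,ITIH4,PSAP,PTGDS,RNASE1,SERPINA3,SLURP1,TF,YWHAZ
Diabetes mellitus, non-insulin-dependent	AGT,ALB,APOA1,APOA4,CLU,FGA,GC,GRN,HBA1,PTGDS,RNASE1,SERPINA3,TF
Schizophrenia	APOA1,APOH,CLU,GC,GRN,ITIH4,PSAP,PTGDS,RNASE1,SERPINA3,SHISA5,TF,YWHAZ
Hypertensive disease	AGT,ALB,APOA1,CLU,FGA,GC,GRN,PTGDS,RNASE1,SERPINA3,TF,YWHAZ
Liver carcinoma	AGT,ALB,APOA1,APOA4,APOH,CLU,FGA,GC,GRN,PTGDS,UMOD,YWHAZ
Diabetes mellitus	AGT,ALB,APOA1,APOA4,APOH,CLU,FGA,GC,GRN,PTGDS,UMOD,YWHAZ
Diabetes	AGT,ALB,APOA1,APOA4,APOH,CLU,GC,HBA1,PTGDS,SERPINA3,UMOD,YWHAZ
Atherosclerosis	AGT,ALB,APOA1,APOA4,APOH,CLU,GC,HBA1,PTGDS,SERPINA3,UMOD,YWHAZ
Arteriosclerosis	AGT,ALB,APOA1,APOH,CLU,FGA,GC,HBA1,RNASE1,SERPINA3,UMOD,YWHAZ
Alzheimer's disease	AGT,ALB,APOA1,APOA4,APOH,CLU,GC,GRN,RNASE1,SERPINA3,TF,YWHAZ
Asthma	AGT,APOA1,GC,IGHG1,ORM1,PSAP,PTGDS,RNASE2,SERPINA3,TF,YWHAZ
Obesity	AGT,ALB,APOA1,APOA4,APOH,CLU,FGA,HBA1,TF,UMOD,YWHAZ
Cardiovascular Diseases	AGT,ALB,APOA1,APOA4,APOH,FGA,HBA1,RNASE1,RNASE2,SERPINA3,TF
Cerebrovascular accident	AGT,APOA1,CLU,GC,GRN,PSAP,PTGDS,RNASE1,SERPINA3,TF,YWHAZ
Malignant neoplasm of prostate	AGT,ALB,APOA1,APOA4,FGA,GC,GRN,ORM1,PTGDS,TF,YWHAZ
Prostate carcinoma	AGT,APOA1,CLU,GC,GRN,PSAP,PTGDS,RNASE1,SERPINA3,TF,YWHAZ
Mammary Neoplasms	AGT,ALB,CLU,GRN,HBA1,PSAP,PTGDS,RNASE1,SLURP1,YWHAZ
Colorectal Cancer	AGT,ALB,APOA1,CLU,GC,ORM2,PSAP,PTGDS,RNASE1,YWHAZ
Neoplasm metastasis	AGT,CLU,GC,GRN,IGK,PSAP,PTGDS,RNASE1,UMOD,YWHAZ
Carcinogenesis	AGT,ALB,APOA1,CLU,GRN,PSAP,RNASE1,SERPINA3,TF,YWHAZ
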