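disease_name	genes
Asthma	GC,IGHG1,ORM1,PSAP,PTGDS,RNASE2,SERPING1,TF
Obesity	F2,FGA,GC,PTGDS,RBP4,SERPING1,TF
Alzheimer's disease	AMBP,F2,GC,IGK,PSAP,PTGDS,TF
Malignant neoplasm of breast	F2,FGA,GC,ORM1,PTGDS,RBP4,TF
Atherosclerosis	AMBP,F2,FGA,GC,PTGDS,RBP4
Arteriosclerosis	AMBP,F2,GC,PSAP,PTGDS,TF
Breast carcinoma	F2,FGA,GC,PTGDS,RBP4,TF
Diabetes mellitus, non-insulin-dependent	AMBP,F2,FGA,GC,PTGDS,RBP4
Malignant neoplasm of prostate	F2,GC,ORM2,PSAP,PTGDS
Diabetes mellitus	AMBP,F2,FGA,GC,TF
Drug-induced liver injury	F2,GC,RBP4,SERPING1,TF
Cardiovascular diseases	GC,PSAP,PTGDS,RBP4,TF
Liver carcinoma	GC,PSAP,PTGDS,RBP4,TF
Colorectal cancer	AMBP,F2,FGA,RBP4,TF
Prostate carcinoma	AMBP,F2,GC,PTGDS,RBP4
Melanoma	F2,FGA,GC,TF
Mammary neoplasms	F2,FGA,RNASE2,TF
Malignant neoplasm of ovary	F2,GC,PSAP,PTGDS
Colorectal carcinoma	F2,FGA,GC,RBP4
Diabetes	F2,GC,PTGDS,RBP4
Diabetic nephropathy	GC,PTGDS,RBP4,TF
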