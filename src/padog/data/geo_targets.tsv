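dataset_id	geo_accession	target_set_id	condition	tissue
D01	GSE1297	hsa05010	Alzheimer's disease	Hippocampal CA1
D02	GSE5281	hsa05010	Alzheimer's disease	Brain, entorhinal cortex
D03	GSE5281	hsa05010	Alzheimer's disease	Brain, hippocampus
D04	GSE5281	hsa05010	Alzheimer's disease	Brain, primary visual cortex
D05	GSE20153	hsa05012	Parkinson's disease	Lymphoblasts
D06	GSE20291	hsa05012	Parkinson's disease	Postmortem brain putamen
D07	GSE8762	hsa05016	Huntington's disease	Lymphocytes (blood)
D08	GSE4107	hsa05210	Colorectal cancer	Mucosa
D09	GSE8671	hsa05210	Colorectal cancer	Colon
D10	GSE9348	hsa05210	Colorectal cancer	Colon
D11	GSE14762	hsa05211	Renal cancer	Kidney
D12	GSE781	hsa05211	Renal cancer	Kidney
D13	GSE15471	hsa05212	Pancreatic cancer	Pancreas
D14	GSE16515	hsa05212	Pancreatic cancer	Pancreas
D15	GSE19728	hsa05214	Glioma	Brain
D16	GSE21354	hsa05214	Glioma	Brain, spine
D17	GSE6956	hsa05215	Prostate cancer	Prostate
D18	GSE6956	hsa05215	Prostate cancer	Prostate
D19	GSE3467	hsa05216	Thyroid cancer	Thyroid
D20	GSE3678	hsa05216	Thyroid cancer	Thyroid
D21	GSE9476	hsa05221	Acute myeloid leukemia	Blood, bone marrow
D22	GSE18842	hsa05223	Non-small cell lung cancer	Lung
D23	GSE19188	hsa05223	Non-small cell lung cancer	Lung
D24	GSE3585	hsa05414	Dilated cardiomyopathy	Heart
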