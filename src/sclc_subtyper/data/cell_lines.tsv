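cell_line	other_id	subtype	origin	chemotherapy	culture_type
DMS153	CRL-2064	SCLC-A	Metastatic	Post-chemo	Semi-adherent
DMS53	CRL-2062	SCLC-A	Lung	Chemo-naive	Adherent
H146	HTB-173	SCLC-A	Metastatic	Chemo-naive	Suspension
H1688	CCL-257	SCLC-A	Metastatic	Chemo-naive	Adherent
H1882	CRL-5903	SCLC-A	Metastatic	N/A	Adherent
H209	HTB-172	SCLC-A	Metastatic	Chemo-naive	Suspension
H378	CRL-5808	SCLC-A	Lung	Post-chemo	Suspension
SHP77	CRL-2195	SCLC-A	Lung	N/A	Adherent
GLC4	N/A	SCLC-N	Pleural eff.	Chemo-naive	Suspension
H1694	CRL-5888	SCLC-N	Lung	N/A	Semi-adherent
H2171	CRL-5929	SCLC-N	Pleural eff.	Post-chemo	Suspension
H446	HTB-171	SCLC-N	Pleural eff.	N/A	Adherent
H524	CRL-5831	SCLC-N	Metastatic	Post-chemo	Suspension
H82	HTB-175	SCLC-N	Metastatic	N/A	Semi-adherent
N417	CRL-5809	SCLC-N	Lung	N/A	Suspension
COR-L311	N/A	SCLC-P	Lung	Post-chemo	Suspension
H1048	CRL-5853	SCLC-P	Pleural eff.	N/A	Adherent
H211	CRL-5824	SCLC-P	Lung	Post-chemo	Suspension
H526	CRL-5811	SCLC-P	Metastatic	Chemo-naive	Suspension
CRL-2066	DMS 114	SCLC-Y	Lung	Chemo-naive	Adherent
CRL-2177	SW1271	SCLC-Y	Lung	N/A	Adherent
H1341	CRL-5864	SCLC-Y	Metastatic	N/A	Adherent
H196	CRL-5823	SCLC-Y	Pleural eff.	Post-chemo	Adherent
H372	N/A	SCLC-Y	Metastatic	N/A	Adherent
H841	CRL-5845	SCLC-Y	Lung	Post-chemo	Adherent
HLHE	N/A	SCLC-Y	Metastatic	N/A	Adherent
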