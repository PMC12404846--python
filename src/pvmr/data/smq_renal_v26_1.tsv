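pt	scope
Acute kidney injury	AKI_SMQ_NARROW
Renal failure acute	AKI_SMQ_NARROW
Acute prerenal failure	AKI_SMQ_NARROW
Acute phosphate nephropathy	AKI_SMQ_NARROW
Anuria	AKI_SMQ_NARROW
Azotemia	AKI_SMQ_NARROW
Continuous hemodiafiltration	AKI_SMQ_NARROW
Dialysis	AKI_SMQ_NARROW
Fetal renal impairment	AKI_SMQ_NARROW
Hemodialysis	AKI_SMQ_NARROW
Hemofiltration	AKI_SMQ_NARROW
Neonatal anuria	AKI_SMQ_NARROW
Nephropathy toxic	AKI_SMQ_NARROW
Oliguria	AKI_SMQ_NARROW
Peritoneal dialysis	AKI_SMQ_NARROW
Prerenal failure	AKI_SMQ_NARROW
Renal failure	AKI_SMQ_NARROW
Renal failure neonatal	AKI_SMQ_NARROW
Renal impairment	AKI_SMQ_NARROW
Renal impairment neonatal	AKI_SMQ_NARROW
Subacute kidney injury	AKI_SMQ_NARROW
Artificial kidney device user	CKD_SMQ_NARROW
Azotemia	CKD_SMQ_NARROW
Renal failure chronic	CKD_SMQ_NARROW
Chronic kidney disease	CKD_SMQ_NARROW
Renal osteodystrophy	CKD_SMQ_NARROW
Chronic kidney disease-mineral and bone disorder	CKD_SMQ_NARROW
Coma uremic	CKD_SMQ_NARROW
Diabetic end stage renal disease	CKD_SMQ_NARROW
Dialysis	CKD_SMQ_NARROW
Dialysis device insertion	CKD_SMQ_NARROW
End stage renal disease	CKD_SMQ_NARROW
Erythropoietin deficiency anemia	CKD_SMQ_NARROW
Glomerulonephritis chronic	CKD_SMQ_NARROW
Hemodialysis	CKD_SMQ_NARROW
Hemofiltration	CKD_SMQ_NARROW
Hepatorenal failure	CKD_SMQ_NARROW
High turnover osteopathy	CKD_SMQ_NARROW
Hyperparathyroidism secondary	CKD_SMQ_NARROW
Kidney fibrosis	CKD_SMQ_NARROW
Renal interstitial fibrosis	CKD_SMQ_NARROW
Low turnover osteopathy	CKD_SMQ_NARROW
Metabolic nephropathy	CKD_SMQ_NARROW
Nephrogenic anemia	CKD_SMQ_NARROW
Nephrogenic fibrosing dermopathy	CKD_SMQ_NARROW
Nephrogenic systemic fibrosis	CKD_SMQ_NARROW
Nephrosclerosis	CKD_SMQ_NARROW
Oedema due to renal disease	CKD_SMQ_NARROW
Pericarditis uremic	CKD_SMQ_NARROW
Peritoneal dialysis	CKD_SMQ_NARROW
Renal and liver transplant	CKD_SMQ_NARROW
Renal and pancreas transplant	CKD_SMQ_NARROW
Renal failure	CKD_SMQ_NARROW
Renal replacement therapy	CKD_SMQ_NARROW
Renal rickets	CKD_SMQ_NARROW
Renal transplant	CKD_SMQ_NARROW
Uremia odor	CKD_SMQ_NARROW
Uremic acidosis	CKD_SMQ_NARROW
Uremic encephalopathy	CKD_SMQ_NARROW
Uremic gastropathy	CKD_SMQ_NARROW
Uremic myopathy	CKD_SMQ_NARROW
Uremic neuropathy	CKD_SMQ_NARROW
Uremic pruritus	CKD_SMQ_NARROW
Uridrosis	CKD_SMQ_NARROW
Urinary incontinence	SOC_RENAL_URINARY
Urinary hesitation	SOC_RENAL_URINARY
Kidney enlargement	SOC_RENAL_URINARY
Renal tubular necrosis	SOC_RENAL_URINARY
Paroxysmal nocturnal haemoglobinuria	SOC_RENAL_URINARY
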