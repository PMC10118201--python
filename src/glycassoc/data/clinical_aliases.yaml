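# Alias map: canonical clinical column name -> acceptable file headers.
# Matching is case-insensitive; extend or override on first contact with a
# new sheet layout.
age: [age, "age (years)", age_years, dob_age]
gdm_status: [gdm_status, gdm, status, group, "gdm status", diagnosis]
fasting_glucose: [fasting_glucose, "fasting glucose", fpg, glucose_0,
                  "fasting glucose (mmol/l)", glu0]
hba1c_mmol_mol: [hba1c_mmol_mol, "hba1c (mmol/mol)", hba1c_ifcc]
hba1c_pct: [hba1c_pct, "hba1c (%)", hba1c_percent, hba1c_ngsp]
fasting_insulin: [fasting_insulin, "fasting insulin", insulin_0,
                  "fasting insulin (pmol/l)", ins0]
homa2_ir: [homa2_ir, "homa2-ir", homa_ir, "homa2 ir"]
homa2_pct_b: [homa2_pct_b, "homa2-%b", "homa2-b", "homa2 %b", homa2_b, "homa2-b (%)"]
triglycerides: [triglycerides, tg, trig, "triglycerides (mmol/l)"]
hdl: [hdl, hdl_cholesterol, "hdl-cholesterol", "hdl (mmol/l)"]
total_cholesterol: [total_cholesterol, cholesterol, chol, tc,
                    "total cholesterol", "total cholesterol (mmol/l)"]
total_proteins: [total_proteins, "total proteins", tp, "total proteins (g/l)"]
urate: [urate, "uric acid", "urate (umol/l)", ua]
alt: [alt, "alt (u/l)", gpt]
ast: [ast, "ast (u/l)", got]
ggt: [ggt, "ggt (u/l)", gamma_gt]
fructosamine: [fructosamine, "fructosamine (umol/l)", fra]
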