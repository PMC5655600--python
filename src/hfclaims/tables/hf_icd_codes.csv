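icd_code,nyha_label,description
I50.0,OTHER,Right ventricular failure
I50.00,OTHER,Primary right ventricular failure
I50.01,OTHER,Secondary right ventricular failure
I50.1,OTHER,Left ventricular failure
I50.11,I,Left ventricular failure NYHA class I
I50.12,II,Left ventricular failure NYHA class II
I50.13,III,Left ventricular failure NYHA class III
I50.14,IV,Left ventricular failure NYHA class IV
I50.19,OTHER,Left ventricular failure NYHA class not specified
I50.9,OTHER,Heart failure unspecified
I11.0,OTHER,Hypertensive heart disease with (congestive) heart failure
I13.0,OTHER,Hypertensive heart and renal disease with (congestive) heart failure
I13.2,OTHER,Hypertensive heart and renal disease with both (congestive) heart failure and renal failure
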