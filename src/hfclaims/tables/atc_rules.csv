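atc_prefix,drug_classes,note
C09A,ACEI,ACE inhibitors plain
C09B,ACEI,ACE inhibitor combinations (default constituent)
C09BA,ACEI;DIURETIC,ACE inhibitors and diuretics
C09C,ARB,Angiotensin II receptor blockers plain
C09D,ARB,ARB combinations (default constituent)
C09DA,ARB;DIURETIC,ARBs and diuretics
C07,BETA_BLOCKER,Beta blocking agents
C07B,BETA_BLOCKER;DIURETIC,Beta blockers and thiazides
C07C,BETA_BLOCKER;DIURETIC,Beta blockers and other diuretics
C07D,BETA_BLOCKER;DIURETIC,Beta blockers plus thiazides plus other diuretics
C03,DIURETIC,Diuretics
C03DA01,MRA,Spironolactone
C03DA04,MRA,Eplerenone
C01,OTHER_CV,Cardiac therapy
C02,OTHER_CV,Antihypertensives
C04,OTHER_CV,Peripheral vasodilators
C05,OTHER_CV,Vasoprotectives
C08,OTHER_CV,Calcium channel blockers
C10,OTHER_CV,Lipid modifying agents
B01AC,OTHER_CV,Platelet aggregation inhibitors
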