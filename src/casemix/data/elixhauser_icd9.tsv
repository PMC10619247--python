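# Elixhauser comorbidity definitions, ICD-9-CM.
# Columns (tab-separated): key, display_name, icd9_tokens (comma-separated single codes
# or low-high ranges), drg_screen (comma-separated DRG numbers, number ranges, or named
# DRG groups: Cardiac, Renal, Liver, Lymphoma, Cancer).
# The two hypertension sub-lists (uncomplicated / complicated) are combined into a single
# condition; its DRG screen is the union of the sub-rows' screens.
congestive_heart_failure	Congestive heart failure	398.91,402.11,402.91,404.11,404.13,404.91,404.93,428.0-428.9	Cardiac
cardiac_arrhythmias	Cardiac arrhythmias	426.10,426.11,426.13,426.2-426.53,426.6-426.89,427.0,427.2,427.31,427.60,427.9,785.0,V45.0,V53.3	Cardiac
valvular_disease	Valvular disease	093.20-093.24,394.0-397.1,424.0-424.91,746.3-746.6,V42.2,V43.3	Cardiac
pulmonary_circulation_disorders	Pulmonary circulation disorders	416.0-416.9,417.9	Cardiac,88
peripheral_vascular_disorders	Peripheral vascular disorders	440.0-440.9,441.2,441.4,441.7,441.9,443.1-443.9,447.1,557.1,557.9,V43.4	130-131
hypertension	Hypertension (combined)	401.1,401.9,402.10,402.90,404.10,404.90,405.11,405.19,405.91,405.99	134,Cardiac,Renal
paralysis	Paralysis	342.0-342.12,342.9-344.9	5,14-17
other_neurological_disorders	Other neurological disorders	331.9,332.0,333.4,333.5,334.0-335.9,340,341.1-341.9,345.00-345.11,345.40-345.51,345.80-345.91,348.1,348.3,780.3,784.3	1-35
chronic_pulmonary_disease	Chronic pulmonary disease	490-492.8,493.00-493.91,494,495.0-505,506.4	88,96-98
diabetes_uncomplicated	Diabetes, uncomplicated	250.00-250.33	294-295
diabetes_complicated	Diabetes, complicated	250.40-250.73,250.90-250.93	294-295
hypothyroidism	Hypothyroidism	243-244.2,244.8,244.9	290,300-301
renal_failure	Renal failure	403.11,403.91,404.12,404.92,585,586,V42.0,V45.1,V56.0,V56.8	302,316-317
liver_disease	Liver disease	070.32,070.33,070.54,456.0,456.1,456.20,456.21,571.0,571.2,571.3,571.40-571.49,571.5,571.6,571.8,571.9,572.3,572.8,V42.7	Liver
peptic_ulcer_disease	Peptic ulcer disease excluding bleeding	531.70,531.90,532.70,532.90,533.70,533.90,534.70,534.90,V12.71	174-178
aids_hiv	AIDS/HIV	042-044.9	488-490
lymphoma	Lymphoma	200.00-202.38,202.50-203.01,203.8-203.81,238.6,273.3,V10.71,V10.72,V10.79	Lymphoma
metastatic_cancer	Metastatic cancer	196.0-199.1	Cancer
solid_tumor	Solid tumor without metastasis	140.0-172.9,174.0-175.9,179-195.8,V10.00-V10.9	Cancer
rheumatoid_arthritis	Rheumatoid arthritis / collagen vascular disease	701.0,710.0-710.9,714.0-714.9,720.0-720.9,725	240-241
coagulopathy	Coagulopathy	2860-2869,287.1,287.3-287.5	397
obesity	Obesity	278.0	288,296-298
weight_loss	Weight loss	260-263.9	296-298
fluid_electrolyte_disorders	Fluid and electrolyte disorders	276.0-276.9	296-298
blood_loss_anemia	Blood loss anemia	2800	395-396
deficiency_anemias	Deficiency anemias	280.1-281.9,285.9	395-396
alcohol_abuse	Alcohol abuse	291.1,291.2,291.5,291.8,291.9,303.90-303.93,305.00-305.03,V113	433-437
drug_abuse	Drug abuse	292.0,292.82-292.89,292.9,304.00-304.93,305.20-305.93	433-437
psychoses	Psychoses	295.00-298.9,299.10-299.11	430
depression	Depression	300.4,301.12,309.0,309.1,311	426
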