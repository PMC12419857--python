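# PhenoAge (phenotypic age) Gompertz mortality-score coefficients.
# Provenance: Levine ME, Lu AT, Quach A, et al. "An epigenetic biomarker of
# aging for lifespan and healthspan." Aging (Albany NY). 2018;10(4):573-591
# (Table: mortality score trained on NHANES III, 10-year horizon).
# version: 1.0
# Units are the NHANES training units; `transform` is applied to the raw
# marker value before weighting (log = natural log).
marker,transform,unit,weight
intercept,none,,-19.9067
albumin,none,g/L,-0.0336
creatinine,none,umol/L,0.0095
glucose,none,mmol/L,0.1953
crp,log,mg/dL,0.0954
lymphocyte_pct,none,%,-0.0120
mcv,none,fL,0.0268
rdw,none,%,0.3306
alkaline_phosphatase,none,U/L,0.00188
wbc,none,1e9 cells/L,0.0554
chronological_age,none,years,0.0804
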