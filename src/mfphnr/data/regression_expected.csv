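# Published OAG structure-function regressions (RAD on GCL thickness):
# slope estimate, 95% CI, R^2 and p, used for reconciliation checks.
rad_region_type,rad_region,gcl_region_type,gcl_region,estimate,ci_low,ci_high,r2,p
ring,R1,area,Area1,0.75,0.57,0.92,0.8,<0.001
ring,R2,area,Area2,0.53,0.33,0.74,0.62,<0.001
ring,R3+R4,area,Area3,0.56,0.25,0.88,0.43,0.001
sector,ST,sector,ST,0.09,0.05,0.14,0.53,<0.001
sector,IT,sector,IT,0.1,0.04,0.16,0.39,0.002
sector,IN,sector,IN,0.06,0.01,0.11,0.3,0.009
sector,SN,sector,SN,0.05,0.02,0.08,0.41,0.001
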