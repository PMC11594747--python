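# Control-derived one-sided lower normative limits (95% CL) for each region
# and measure, as published alongside the cohort; used verbatim for
# abnormality classification in 'supplied' mode.
region_type,region,measure,limit
ring,R1,mfPhNR_RAD,26.92
area,Area1,GCL_T,43.51
ring,R2,mfPhNR_RAD,12.71
area,Area2,GCL_T,32.2
ring,R3+R4,mfPhNR_RAD,6.72
area,Area3,GCL_T,23.27
sector,ST,mfPhNR_RAD,4.41
sector,ST,GCL_T,26.03
sector,IT,mfPhNR_RAD,4.41
sector,IT,GCL_T,27.4
sector,IN,mfPhNR_RAD,4.56
sector,IN,GCL_T,28.05
sector,SN,mfPhNR_RAD,4.59
sector,SN,GCL_T,28.83
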