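# Published group summary statistics (mean, SD, n) for the 20-eye control
# group and the 21-eye OAG group, per region and measure.
group,region_type,region,measure,mean,sd,n
control,ring,R1,mfPhNR_RAD,30.047,4.616,20
patient,ring,R1,mfPhNR_RAD,15.924,5.188,21
control,area,Area1,GCL_T,45.224,3.865,20
patient,area,Area1,GCL_T,26.829,6.207,21
control,ring,R2,mfPhNR_RAD,14.737,5.073,20
patient,ring,R2,mfPhNR_RAD,6.795,2.236,21
control,area,Area2,GCL_T,33.15,2.16,20
patient,area,Area2,GCL_T,23.886,3.27,21
control,ring,R3+R4,mfPhNR_RAD,7.175,0.962,20
patient,ring,R3+R4,mfPhNR_RAD,4.271,1.43,21
control,area,Area3,GCL_T,24.03,1.707,20
patient,area,Area3,GCL_T,20.19,1.663,21
control,sector,ST,mfPhNR_RAD,5.041,1.431,20
patient,sector,ST,mfPhNR_RAD,2.2,0.716,21
control,sector,ST,GCL_T,27.2,2.575,20
patient,sector,ST,GCL_T,21.029,5.288,21
control,sector,IT,mfPhNR_RAD,5.127,1.624,20
patient,sector,IT,mfPhNR_RAD,1.967,0.687,21
control,sector,IT,GCL_T,28.486,2.444,20
patient,sector,IT,GCL_T,19.776,4.104,21
control,sector,IN,mfPhNR_RAD,5.382,1.859,20
patient,sector,IN,mfPhNR_RAD,1.681,0.434,21
control,sector,IN,GCL_T,28.941,2.021,20
patient,sector,IN,GCL_T,23.19,3.793,21
control,sector,SN,mfPhNR_RAD,5.314,1.637,20
patient,sector,SN,mfPhNR_RAD,1.557,0.407,21
control,sector,SN,GCL_T,29.632,1.812,20
patient,sector,SN,GCL_T,24.067,4.996,21
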