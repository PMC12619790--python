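stratum_level,stratum_label,kpi_id,numerator,denominator,value,displayable,n_missing
OVERALL,ALL,KPI1_BOTTLE,174,29,6.0,True,1
OVERALL,ALL,KPI1_EPISODE,174,9,19.33,True,0
OVERALL,ALL,KPI2,3,9,33.3,True,0
OVERALL,ALL,KPI3,2,3,66.7,True,0
OVERALL,ALL,KPI4A,1,4,25.0,True,0
OVERALL,ALL,KPI4B,2,4,50.0,True,0
OVERALL,ALL,POSITIVITY,6,9,66.7,True,0
OVERALL,ALL,BOTTLES_PER_EPISODE,30,9,3.33,True,0
OVERALL,ALL,EPISODES_PER_PATIENT,9,8,1.1,True,0
CENTER,C1,KPI1_BOTTLE,108,18,6.0,True,0
CENTER,C1,KPI1_EPISODE,108,5,21.6,True,0
CENTER,C1,KPI2,1,5,20.0,True,0
CENTER,C1,KPI3,1,2,50.0,True,0
CENTER,C1,KPI4A,1,3,33.3,True,0
CENTER,C1,KPI4B,2,3,66.7,True,0
CENTER,C1,POSITIVITY,4,5,80.0,True,0
CENTER,C1,BOTTLES_PER_EPISODE,18,5,3.6,True,0
CENTER,C1,EPISODES_PER_PATIENT,5,4,1.2,True,0
CENTER,C2,KPI1_BOTTLE,66,11,6.0,True,1
CENTER,C2,KPI1_EPISODE,66,4,16.5,True,0
CENTER,C2,KPI2,2,4,50.0,True,0
CENTER,C2,KPI3,1,1,100.0,True,0
CENTER,C2,KPI4A,0,1,0.0,True,0
CENTER,C2,KPI4B,0,1,0.0,True,0
CENTER,C2,POSITIVITY,2,4,50.0,True,0
CENTER,C2,BOTTLES_PER_EPISODE,12,4,3.0,True,0
CENTER,C2,EPISODES_PER_PATIENT,4,4,1.0,True,0
AREA,MEDICAL,KPI1_BOTTLE,108,18,6.0,True,1
AREA,MEDICAL,KPI1_EPISODE,108,6,18.0,True,0
AREA,MEDICAL,KPI2,2,6,33.3,True,0
AREA,MEDICAL,KPI3,0,0,,False,0
AREA,MEDICAL,KPI4A,1,4,25.0,True,0
AREA,MEDICAL,KPI4B,2,4,50.0,True,0
AREA,MEDICAL,POSITIVITY,4,6,66.7,True,0
AREA,MEDICAL,BOTTLES_PER_EPISODE,19,6,3.17,True,0
AREA,MEDICAL,EPISODES_PER_PATIENT,6,5,1.2,True,0
AREA,ICU,KPI1_BOTTLE,66,11,6.0,True,0
AREA,ICU,KPI1_EPISODE,66,3,22.0,True,0
AREA,ICU,KPI2,1,3,33.3,True,0
AREA,ICU,KPI3,2,3,66.7,True,0
AREA,ICU,KPI4A,0,0,,False,0
AREA,ICU,KPI4B,0,0,,False,0
AREA,ICU,POSITIVITY,2,3,66.7,True,0
AREA,ICU,BOTTLES_PER_EPISODE,11,3,3.67,True,0
AREA,ICU,EPISODES_PER_PATIENT,3,3,1.0,True,0
SERVICE,MED-A,KPI1_BOTTLE,72,12,6.0,False,0
SERVICE,MED-A,KPI1_EPISODE,72,3,24.0,False,0
SERVICE,MED-A,KPI2,0,3,0.0,False,0
SERVICE,MED-A,KPI3,0,0,,False,0
SERVICE,MED-A,KPI4A,1,3,33.3,True,0
SERVICE,MED-A,KPI4B,2,3,66.7,True,0
SERVICE,MED-A,POSITIVITY,3,3,100.0,True,0
SERVICE,MED-A,BOTTLES_PER_EPISODE,12,3,4.0,True,0
SERVICE,MED-A,EPISODES_PER_PATIENT,3,2,1.5,True,0
SERVICE,ICU-A,KPI1_BOTTLE,36,6,6.0,False,0
SERVICE,ICU-A,KPI1_EPISODE,36,2,18.0,False,0
SERVICE,ICU-A,KPI2,1,2,50.0,False,0
SERVICE,ICU-A,KPI3,1,2,50.0,False,0
SERVICE,ICU-A,KPI4A,0,0,,False,0
SERVICE,ICU-A,KPI4B,0,0,,False,0
SERVICE,ICU-A,POSITIVITY,1,2,50.0,True,0
SERVICE,ICU-A,BOTTLES_PER_EPISODE,6,2,3.0,True,0
SERVICE,ICU-A,EPISODES_PER_PATIENT,2,2,1.0,True,0
SERVICE,MED-B,KPI1_BOTTLE,36,6,6.0,False,1
SERVICE,MED-B,KPI1_EPISODE,36,3,12.0,False,0
SERVICE,MED-B,KPI2,2,3,66.7,False,0
SERVICE,MED-B,KPI3,0,0,,False,0
SERVICE,MED-B,KPI4A,0,1,0.0,True,0
SERVICE,MED-B,KPI4B,0,1,0.0,True,0
SERVICE,MED-B,POSITIVITY,1,3,33.3,True,0
SERVICE,MED-B,BOTTLES_PER_EPISODE,7,3,2.33,True,0
SERVICE,MED-B,EPISODES_PER_PATIENT,3,3,1.0,True,0
SERVICE,ICU-B,KPI1_BOTTLE,30,5,6.0,False,0
SERVICE,ICU-B,KPI1_EPISODE,30,1,30.0,False,0
SERVICE,ICU-B,KPI2,0,1,0.0,False,0
SERVICE,ICU-B,KPI3,1,1,100.0,False,0
SERVICE,ICU-B,KPI4A,0,0,,False,0
SERVICE,ICU-B,KPI4B,0,0,,False,0
SERVICE,ICU-B,POSITIVITY,1,1,100.0,True,0
SERVICE,ICU-B,BOTTLES_PER_EPISODE,5,1,5.0,True,0
SERVICE,ICU-B,EPISODES_PER_PATIENT,1,1,1.0,True,0
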