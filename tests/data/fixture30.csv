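patient_id,age_years,center,area,hospital_service,sample_id,bottle_id,specimen_origin,bottle_type,collected_at,status,organisms,volume_ml
P1,65,C1,MEDICAL,MED-A,S1a,B01,PV,AEROBIC,2023-03-01T08:00,POSITIVE,Staphylococcus epidermidis,5.0
P1,65,C1,MEDICAL,MED-A,S1a,B02,PV,ANAEROBIC,2023-03-01T08:05,NEGATIVE,,7.0
P1,65,C1,MEDICAL,MED-A,S1b,B03,PV,AEROBIC,2023-03-01T08:20,NEGATIVE,,6.0
P1,65,C1,MEDICAL,MED-A,S1b,B04,PV,ANAEROBIC,2023-03-01T08:25,NEGATIVE,,6.0
P1,65,C1,MEDICAL,MED-A,S7a,B05,PV,AEROBIC,2023-03-03T09:00,POSITIVE,Staphylococcus epidermidis,6.0
P1,65,C1,MEDICAL,MED-A,S7a,B06,PV,ANAEROBIC,2023-03-03T09:05,NEGATIVE,,6.0
P1,65,C1,MEDICAL,MED-A,S7b,B07,PV,AEROBIC,2023-03-03T09:20,POSITIVE,Staphylococcus epidermidis,6.0
P1,65,C1,MEDICAL,MED-A,S7b,B08,PV,ANAEROBIC,2023-03-03T09:25,NEGATIVE,,6.0
P2,54,C1,MEDICAL,MED-A,S2a,B09,PV,AEROBIC,2023-04-10T10:00,POSITIVE,Staphylococcus hominis,6.0
P2,54,C1,MEDICAL,MED-A,S2a,B10,PV,ANAEROBIC,2023-04-10T10:02,POSITIVE,Staphylococcus hominis,6.0
P2,54,C1,MEDICAL,MED-A,S2b,B11,PV,AEROBIC,2023-04-10T10:15,NEGATIVE,,6.0
P2,54,C1,MEDICAL,MED-A,S2b,B12,PV,ANAEROBIC,2023-04-10T10:18,NEGATIVE,,6.0
P3,71,C1,ICU,ICU-A,S3a,B13,CVC,AEROBIC,2023-05-02T06:00,POSITIVE,Escherichia coli,8.0
P3,71,C1,ICU,ICU-A,S3a,B14,CVC,ANAEROBIC,2023-05-02T06:03,NEGATIVE,,8.0
P3,71,C1,ICU,ICU-A,S3b,B15,PV,AEROBIC,2023-05-02T06:10,POSITIVE,Escherichia coli,4.0
P3,71,C1,ICU,ICU-A,S3b,B16,PV,ANAEROBIC,2023-05-02T06:12,NEGATIVE,,4.0
P4,80,C1,ICU,ICU-A,S4a,B17,CVC,AEROBIC,2023-05-15T14:00,NEGATIVE,,6.0
P4,80,C1,ICU,ICU-A,S4a,B18,CVC,ANAEROBIC,2023-05-15T14:05,NEGATIVE,,6.0
P5,45,C2,MEDICAL,MED-B,S5a,B19,PV,AEROBIC,2023-06-20T09:30,POSITIVE,Staphylococcus aureus,6.0
P6,59,C2,MEDICAL,MED-B,S6a,B20,PV,AEROBIC,2023-07-04T11:00,NEGATIVE,,6.0
P6,59,C2,MEDICAL,MED-B,S6a,B21,PV,ANAEROBIC,2023-07-04T11:04,NEGATIVE,,6.0
P6,59,C2,MEDICAL,MED-B,S6b,B22,PV,AEROBIC,2023-07-04T11:20,NEGATIVE,,6.0
P6,59,C2,MEDICAL,MED-B,S6b,B23,PV,ANAEROBIC,2023-07-04T11:24,NEGATIVE,,
P7,62,C2,ICU,ICU-B,S8a,B24,CVC,AEROBIC,2023-08-09T07:00,POSITIVE,Candida albicans,6.0
P7,62,C2,ICU,ICU-B,S8a,B25,CVC,ANAEROBIC,2023-08-09T07:05,NEGATIVE,,6.0
P7,62,C2,ICU,ICU-B,S8b,B26,CVC,AEROBIC,2023-08-09T07:30,NEGATIVE,,6.0
P7,62,C2,ICU,ICU-B,S8b,B27,CVC,ANAEROBIC,2023-08-09T07:33,NEGATIVE,,6.0
P7,62,C2,ICU,ICU-B,S8c,B28,CVC,AEROBIC,2023-08-09T07:50,NEGATIVE,,6.0
P8,38,C2,MEDICAL,MED-B,S9a,B29,PV,AEROBIC,2023-09-12T16:00,NEGATIVE,,6.0
P8,38,C2,MEDICAL,MED-B,S9a,B30,PV,ANAEROBIC,2023-09-12T16:05,NEGATIVE,,6.0
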