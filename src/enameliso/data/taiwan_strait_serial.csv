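specimen_id,taxon,epoch,age_years,sample_label,position_index,d13C_enamel_vpdb,d18O_vpdb
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P1,1,,
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P2,2,,
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P3,3,-4.92,-5.26
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P4,4,-3.59,-5.62
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P5,5,-2.93,-6.02
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P6,6,-2.33,-6.96
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P7,7,-2.03,-7.72
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P8,8,-2.28,-6.28
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P9,9,-2.47,-6.08
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P10,10,-1.88,-6.79
NTUM-VP 210127,Palaeoloxodon sp.,pleistocene,5,P11,11,-1.18,-6.11
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S1,1,-2.33,-8.71
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S2,2,-2.03,-7.77
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S3,3,-2.1,-7.03
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S4,4,-1.95,-8.83
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S5,5,-1.28,-6.9
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S6,6,-0.98,-7.16
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S7,7,-1.12,-7.8
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S8,8,-1.42,-8.23
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S9,9,-1.37,-7.82
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S10,10,-1.78,-8.3
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S11,11,-1.39,-7.01
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S12,12,-1.68,-8.11
NTUM-VP 230921,Palaeoloxodon sp.,pleistocene,15.5,S13,13,-1.08,-7.42
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q1,1,-0.92,-6.16
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q2,2,-0.4,-6.44
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q3,3,-1.28,-5.26
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q4,4,-1.22,-6.7
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q5,5,-1.07,-6.29
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q6,6,-1.44,-6.94
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q7,7,-1.29,-6.4
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q8,8,-1.66,-6.88
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q9,9,-1.24,-5.38
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q10,10,-0.96,-6.05
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q11,11,-1.14,-6.23
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q12,12,-1.51,-6.67
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q13,13,-0.38,-6.4
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q14,14,-0.74,-7.31
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q15,15,-0.87,-6.28
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q16,16,-0.64,-6.24
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q17,17,-1.12,-6.43
NTUM-VP 230920,Palaeoloxodon sp.,pleistocene,24-27,Q18,18,-1.32,-5.87
N-000033/NF002445,Elephas maximus,modern,,T1,1,-13.18,-7.11
N-000033/NF002445,Elephas maximus,modern,,T2,2,-13.62,-6.78
N-000033/NF002445,Elephas maximus,modern,,T3,3,-12.84,-6.58
N-000033/NF002445,Elephas maximus,modern,,T4,4,-13.07,-6.75
N-000033/NF002445,Elephas maximus,modern,,T5,5,-13.51,-7.74
N-000033/NF002445,Elephas maximus,modern,,T6,6,-12.9,-6.52
N-000033/NF002445,Elephas maximus,modern,,T7,7,-13.17,-6.94
N-000033/NF002445,Elephas maximus,modern,,T8,8,-12.77,-8.05
N-000033/NF002445,Elephas maximus,modern,,T9,9,-12.27,-6.67
N-000033/NF002445,Elephas maximus,modern,,T10,10,-12.88,-6.11
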