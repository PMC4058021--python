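probe_id,gene_symbol,pathways,direction,os_cutpoint,os_fdr,os_hr,efs_cutpoint,efs_fdr,efs_hr
218979_at,RMI1,FA,BAD,1356,1.E-04,5,1353,6.E-04,3.0
201202_at,PCNA,NER,BAD,3703,1.E-04,4.5,2446,9.E-04,2.2
222777_s_at,WHSC1/MMSET,NHEJ,BAD,1506,3.E-04,3.7,918,3.E-05,2.8
204603_at,EXO1,HR;MMR,BAD,295,8.E-04,3.9,48,4.E-02,1.8
213007_at,FANCI,FA,BAD,648,9.E-04,3.5,179,1.E-02,2.4
226503_at,RIF1,NHEJ,BAD,1273,2.E-03,3.2,1273,2.E-03,2.3
205733_at,BLM,HR,BAD,1450,4.E-03,2.9,1495,2.E-02,1.8
209421_at,MSH2,MMR,BAD,608,3.E-02,2.7,352,3.E-02,1.6
209507_at,RPA3,HR;NER,BAD,3902,3.E-02,3.2,3836,5.E-04,3.1
204123_at,LIG3,NER;BER,BAD,502,3.E-02,2.6,435,4.E-03,2.0
212836_at,POLD3,NER,BAD,262,3.E-02,6.3,247,2.E-02,2.1
205024_s_at,RAD51,HR,BAD,641,3.E-02,2.8,514,5.E-02,1.7
208642_s_at,XRCC5/KU80,NHEJ,BAD,7702,4.E-02,2.9,7626,2.E-03,2.5
235215_at,ERCC4,NER,BAD,1103,4.E-02,2.5,873,1.E-03,2.2
203805_s_at,FANCA,FA,BAD,271,4.E-02,2.2,140,1.E-02,2.4
203422_at,POLD1,NER,BAD,762,5.E-02,2.4,714,1.E-02,2.0
205395_s_at,MRE11A,HR,BAD,544,5.E-02,2.1,542,1.E-02,1.8
203720_s_at,ERCC1,NER,GOOD,1885,4.E-02,0.4,3184,2.E-02,0.4
218961_s_at,PNKP,NHEJ,GOOD,1473,4.E-02,0.4,1346,2.E-03,0.5
221049_s_at,POLL,NHEJ,GOOD,101,5.E-02,0.3,42,5.E-03,0.5
202414_at,ERCC5,NER,GOOD,645,5.E-02,0.5,695,5.E-03,0.5
212672_at,ATM,HR,GOOD,1570,5.E-02,0.5,1575,3.E-02,0.6
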