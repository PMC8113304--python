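name,class,group,areas,loq_ng_g,recovery_pct,ld50_ug_bee,b1,approved_de,df_days,max_conc_ng_g,mean_conc_ng_g,phq_max_reported,mean_phq_reported
Acetamiprid,insecticide,Neonicotinoids,f;v,3,84,15,0,1,11,31,1.3,2.1,0.09
Azoxystrobin,fungicide,Quinone outside inhibitors,f;v,3,123,25,0,1,6,14,0.6,0.6,0.03
Boscalid,fungicide,Succinate dehydrogenase inhibitors,f;v;r,3,105,166,0,1,36,201,7.9,1.2,0.05
Chlorantraniliprole,insecticide,Diamides,f;v,3,120,104,0,1,25,307,13.6,3.0,0.13
Cyprodinil,fungicide,Anilino-pyrimidines,f,3,29,113,0,1,9,193,5.8,1.7,0.05
Difenoconazole,fungicide,Demethylation inhibitors,f;v,3,87,177,0,1,10,48,1.5,0.27,0.01
Diflubenzuron,insecticide,Chitin synthesis inhibitors,f;v;c,3,79,9.1,1,0,2,121,1.3,13,0.14
Dimethenamid,herbicide,Chloroacetamides,f;v;c,3,98,118,0,1,11,121,2.5,1.0,0.02
Dimoxystrobin,fungicide,Quinone outside inhibitors,r,3,108,79,0,1,2,6.1,0.1,0.08,0.001
Fenhexamid,fungicide,Sterol biosynthesis inhibitors,f;v,10,44,102,0,1,10,274,6.3,2.7,0.06
Fenoxycarb,insecticide,Insect growth regulator,f;c,3,96,204,1,0,14,367,5.0,1.8,0.02
Fenpyroximate,insecticide,Pyrazole,f;v;w,3,82,119,0,1,15,99,2.6,0.8,0.02
Flonicamid,insecticide,Flonicamid,f;v;r,3,83,100,0,1,19,35,2.4,0.4,0.02
Fluopyram,fungicide,Succinate dehydrogenase inhibitors,f;v;w,5,125,102,0,1,27,4050,123,40,1.2
Kresoxim-methyl,fungicide,Quinone outside inhibitors,w,5,116,110,0,1,3,10,0.3,0.09,0.002
Methiocarb,insecticide,Carbamates,s.t.,3,94,0.08,0,1,16,14,1.0,170,12.2
Myclobutanil,fungicide,Demethylation inhibitors,f;v;w,5,106,34,0,1,39,334,11.9,9.8,0.4
Penconazole,fungicide,Demethylation inhibitors,f;v;w,3,55,112,0,1,14,24,1.2,0.2,0.01
Pendimethalin,herbicide,Dinitroanilines,c,5,53,101,0,1,17,1810,36.6,18,0.4
Picaridin,insecticide,Piperidines,i.r.,15,82,–,0,1,15,117,5.8,–,–
Pirimicarb,insecticide,Carbamates,f;v;c,3,53,4.0,0,1,3,25,0.5,6.3,0.14
Pyraclostrobin,fungicide,Quinone outside inhibitors,f;v;c,5,100,110,0,1,6,49,1.1,0.44,0.01
Pyrimethanil,fungicide,Anilino-pyrimidines,f;w;c,5,57,100,0,1,9,52,1.8,0.52,0.02
Spirodiclofen,insecticide,Biosynthesis inhibitors,f;v;c,5,4,196,1,1,29,402,15.8,2.1,0.08
Tebuconazole,fungicide,Demethylation inhibitors,f;v;w,5,90,83,0,1,17,4530,98.4,55,1.8
Tebufenozide,insecticide,Diacylhydrazines,f;v;w,3,107,100,0,1,18,412,8.7,4.1,0.09
Thiacloprid,insecticide,Neonicotinoids,f;v;c,3,77,17,0,1,47,258,14.0,15,0.8
Thiophanate-methyl,fungicide,b-Tubulin inhibitors,f;c,10,101,115,0,1,7,59,2.1,0.51,0.02
Trifloxystrobin,fungicide,Quinone outside inhibitors,f;v;c,3,112,110,0,1,64,707,40.6,6.4,0.37
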