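gene,variant_id,disease,group,major_allele,minor_allele,maf,k,n_cases,n_controls,or_value,ci_low,ci_high,p,i2,p_q,venice,fprp,credibility
TERT,rs2736098,Bladder cancer,Overall,C,T,0.3214,5,1863,3381,1.193,1.085,1.313,<0.001,47.8,0.104,ABA,0.006,Strong
TERT,rs2736100,Bladder cancer,Overall,C,A,0.5597,4,1638,3141,0.883,0.803,0.970,0.01,0.0,0.507,ABC,0.152,Weak
CLPTM1L,rs401681,Bladder cancer,Overall,C,T,0.3615,4,1555,2500,0.852,0.771,0.941,0.002,0.0,0.757,AAA,0.029,Strong
CLPTM1L,rs402710,Bladder cancer,Overall,C,T,0.3236,3,1454,2179,0.863,0.772,0.965,0.01,0.0,0.635,AAA,0.156,Strong
TERT,rs2736098,Breast cancer,Caucasian,C,T,0.3004,6,4591,5159,0.834,0.714,0.973,0.021,72.3,0.003,ACC,0.286,Weak
TERT,rs2736100,Colorectal cancer,Caucasian,C,A,0.4980,10,19050,21500,1.070,1.040,1.102,<0.001,0.0,0.700,AAC,<0.001,Moderate
TERT,rs2736100,Esophageal squamous cell carcinoma,Asian,C,A,0.6055,3,2098,2150,0.724,0.664,0.789,<0.001,0.0,0.779,AAA,<0.001,Strong
TERT,rs2853691,Esophageal squamous cell carcinoma,Asian,A,G,0.2486,3,2098,2150,1.304,1.149,1.479,<0.001,40.6,0.186,ABA,0.001,Strong
CLPTM1L,rs401681,Esophageal squamous cell carcinoma,Asian,C,T,0.3386,3,1742,1856,0.867,0.784,0.958,0.005,16.2,0.303,AAA,0.088,Strong
CLPTM1L,rs451360,Esophageal squamous cell carcinoma,Asian,C,A,0.1258,3,2098,2150,0.700,0.610,0.904,<0.001,0.0,0.979,BAA,0.156,Moderate
TERT,rs10069690,Gastric cancer,Asian,C,T,0.1816,4,2470,2236,1.317,1.193,1.454,<0.001,28.5,0.241,ABA,<0.001,Strong
TERT,rs2736100,Gastric cancer,Overall,C,A,0.6270,4,1843,2195,0.751,0.568,0.993,0.044,85.1,<0.001,ACC,0.514,Weak
TERT,rs2853676,Gastric cancer,Asian,T,C,0.7990,4,2182,2400,0.675,0.484,0.942,0.021,89.5,<0.001,ACC,0.428,Weak
TERT,rs2736100,Glioma,Overall,C,A,0.5046,8,5750,8379,0.746,0.666,0.835,<0.001,77.0,<0.001,AAA,<0.001,Strong
TERT,rs2853676,Glioma,Overall,T,C,0.7477,7,5832,8143,0.784,0.743,0.828,<0.001,0.0,0.504,AAA,<0.001,Strong
TERT,rs2736100,Idiopathic pulmonary fibrosis,Asian,C,A,0.5898,3,397,1848,1.788,1.508,2.120,<0.001,0.0,0.910,AAA,<0.001,Strong
TERT,rs2242652,Lung cancer,Asian,G,A,0.1650,3,3631,4013,1.168,1.054,1.294,0.003,0.0,0.562,AAA,0.053,Strong
TERT,rs2736098,Lung cancer,Overall,C,T,0.3199,10,5350,6115,1.212,1.121,1.310,<0.001,47.0,0.049,ABA,<0.001,Strong
TERT,rs2736100,Lung cancer,Overall,C,A,0.5024,27,33918,35844,0.856,0.788,0.931,<0.001,90.9,<0.001,AAA,0.005,Strong
TERT,rs2853677,Lung cancer,Asian,G,A,0.5881,3,1123,1340,0.791,0.704,0.890,<0.001,1.5,0.362,AAA,0.002,Strong
CLPTM1L,rs31489,Lung cancer,Overall,C,A,0.3546,7,13850,14390,0.860,0.813,0.909,<0.001,44.7,0.093,AAA,<0.001,Strong
CLPTM1L,rs401681,Lung cancer,Overall,C,T,0.3600,17,11280,12390,0.885,0.840,0.932,<0.001,35.5,0.073,AAA,<0.001,Strong
CLPTM1L,rs402710,Lung cancer,Overall,C,T,0.3339,16,20135,25250,0.857,0.832,0.883,<0.001,0.0,0.873,AAA,<0.001,Strong
CLPTM1L,rs465498,Lung cancer,Asian,A,G,0.1701,4,8948,9805,0.765,0.723,0.810,<0.001,0.0,0.880,AAA,<0.001,Strong
TERT/CLPTM1L,rs4975616,Lung cancer,Overall,G,A,0.6387,7,11300,8873,1.159,1.108,1.212,<0.001,32.7,0.146,AAA,<0.001,Strong
TERT,rs2736100,Myeloproliferative neoplasms,Overall,C,A,0.5846,7,2436,19204,0.586,0.538,0.637,<0.001,0.0,0.848,AAA,<0.001,Strong
CLPTM1L,rs401681,Pancreatic cancer,Caucasian,C,T,0.4398,3,2591,5383,1.173,1.097,1.255,<0.001,0.0,0.974,AAA,<0.001,Strong
CLPTM1L,rs401681,Skin cancer (melanoma),Caucasian,C,T,0.4415,3,1188,1603,1.285,1.120,1.414,<0.001,23.5,0.270,AAA,0.002,Strong
TERT,rs2736100,Thyroid cancer,Asian,C,A,0.5969,4,2752,2752,0.762,0.657,0.884,<0.001,72.2,0.013,ACC,0.007,Moderate
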