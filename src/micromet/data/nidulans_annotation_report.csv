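feature_id,annotation,mz,adduct,error_ppm
1,Cordycepin,501.194,[2M-H]-,3.88
2,Cordycepin,286.070,[M+Cl]-,5.88
3,Arugosin G,537.255,[M+FA-H]-,9.73
4,Asperfuranone,377.157,[M+FA-H]-,8.43
5,Aspoquinolone A/B,502.165,[M+K-2H]-,2.27
6,Austinol intermediate (C25H30O7),441.192,[M-H]-,0.49
7,Dehydroaustinol,493.131,[M+K-2H]-,7.81
8,Dehydroaustinol,501.177,[M+FA-H]-,1.67
9,Dehydroaustinol,491.149,[M+Cl]-,1.76
10,Dehydroaustinol,455.171,[M-H]-,0.63
11,Dehydrocitreoisocoumarin or 2-acetoacetyl T4HN,137.024,[M-2H]2-,1.60
12,Desacetylaustin or austinol,457.187,[M-H]-,1.22
13,Desacetylaustin or austinol,493.164,[M+Cl]-,0.65
14,Diorcinol,229.085,[M-H]-,6.70
15,Diorcinol,459.178,[2M-H]-,6.26
16,Diorcinol,505.182,[2M+FA-H]-,9.59
17,Emericellamide A,646.354,[M+K-2H]-,6.66
18,Emericellamide A,644.380,[M+Cl]-,0.05
19,Emericellamide C/D,640.393,[M+FA-H]-,0.66
20,Emericellamide C/D,630.365,[M+Cl]-,0.96
21,Emericellamide C/D,632.339,[M+K-2H]-,6.08
22,Emericellamide E/F,658.395,[M+Cl]-,0.17
23,Emericellamide E/F,668.425,[M+FA-H]-,1.34
24,Emericellamide E/F,660.375,[M+K-2H]-,0.60
25,Emericellin,393.172,[M-H]-,2.16
26,Emericellin,815.386,[2M-H]-,7.26
27,Emodic acid,336.977,[M+K-2H]-,2.86
28,A heptaketide (C15H24O2),257.154,[M+Na-2H]-,7.21
29,Isoaustinone,471.202,[M+FA-H]-,1.88
30,Isoaustinone,463.153,[M+K-2H]-,0.39
31,Nidulalin A or B,301.072,[M-H]-,0.73
32,Nidulol,239.057,[M+FA-H]-,2.41
33,Variecoxanthone A,679.254,[2M-H]-,1.74
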