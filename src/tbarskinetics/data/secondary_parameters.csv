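sample,k277,k281,k289,k293,ea,ea_sd,k0,k0_sd,c,tc
Allspice,0.07334,0.09552,0.19964,0.29104,58834,339,8.9e9,1.2e9,0.0997,294.14
Basil,0.07907,0.1081,0.21726,0.32914,59854,286,1.4e10,1.9e9,0.1055,302.28
Bay leaf,0.08662,0.10659,0.23613,0.33710,59207,412,1.1e10,1.9e9,0.1039,302.02
Black seed,0.07215,0.09225,0.18412,0.27031,56185,1848,3.3e9,2.8e9,0.0946,305.72
Caraway,0.07046,0.09024,0.16957,0.24334,52453,217,5.2e8,4.6e7,0.0876,308.06
Cardamom,0.06906,0.08997,0.16608,0.23905,52239,108,4.7e8,2.1e7,0.0868,308.44
Clove,0.06834,0.08858,0.15796,0.23645,51655,1042,3.8e8,1.5e8,0.0860,308.86
Control,0.12067,0.1651,0.37407,0.54319,64549,505,1.7e11,3.8e10,0.1164,296.02
Garlic,0.08689,0.11049,0.25619,0.39282,65007,314,1.4e11,1.9e10,0.1192,299.420
Nutmeg,0.07571,0.09882,0.20005,0.30057,58393,684,7.4e9,2.1e9,0.1011,303.71
Onion,0.10824,0.16924,0.3528,0.44135,59926,372,2.2e10,3.3e9,0.0965,298.94
Oregano,0.07801,0.10292,0.21090,0.31159,58800,177,8.9e9,7.4e8,0.1020,303.11
Rosemary,0.08209,0.10839,0.22926,0.34830,61333,883,2.9e10,1.08e10,0.1094,301.34
Thyme,0.07207,0.09067,0.17193,0.24861,52572,556,5.7e8,1.1e8,0.0869,307.89
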