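extract,teac_dpph,tpc
Allspice,555,31.61
Basil,134.7,14.81
Bay leaf,231.9,22.56
Black seed,7.59,2.46
Cardamom,5.45,1.24
Caraway,20.2,2.39
Clove,1443,167.2
Garlic,14.8,3.6
Nutmeg,22.22,3.89
Onion,5.74,7.05
Oregano,171.6,20.7
Rosemary,50.4,4.66
Thyme,278.3,23.5
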