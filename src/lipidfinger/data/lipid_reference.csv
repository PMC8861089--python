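name,lipid_class,formula,adduct,ion_label,role,tof_mz,p_adj,log2fc,mz_printed,mz_fticr,ppm_printed,inv_k0,ccs
LysoPC(14:0/0:0),LysoPC,C22H46NO7P,M+H,[LPC 14:0]+,marker,468.31,0.003,0.9,468.3084,468.3085,0.2,1.081,222.9
LysoPC(O-16:0/0:0),LysoPC,C24H52NO6P,M+H,[LPC O-16:0]+,marker,482.36,0.008,0.8,482.3605,482.3605,0.0,1.123,231.3
LysoPC(16:0/0:0),LysoPC,C24H50NO7P,M+H,[LPC 16:0]+,marker,496.35,0.001,1.2,496.3398,496.3398,0.0,1.118,230.1
LysoPC(16:0/0:0),LysoPC,C24H50NO7P,M+Na,[LPC 16:0 + Na]+,marker,518.33,0.008,0.8,518.3217,518.3216,-0.2,1.134,233.1
DG(30:0),DG,C33H64O5,M+H-H2O,[DG 30:0-H2O]+,marker,523.48,0.008,1.9,523.4721,523.4720,-0.2,1.216,249.9
LysoPC(18:0/0:0),LysoPC,C26H54NO7P,M+H,[LPC 18:0]+,marker,524.38,0.002,1.2,524.3711,524.3711,0.0,1.150,236.4
LysoPC(16:0/0:0),LysoPC,C24H50NO7P,M+K,[LPC 16:0 + K]+,marker,534.31,0.005,1.2,534.2956,534.2954,-0.4,1.137,233.6
LysoPC(18:0/0:0),LysoPC,C26H54NO7P,M+Na,[LPC 18:0 + Na]+,marker,546.37,0.010,0.9,546.3530,546.3527,-0.5,1.165,239.2
LysoPC(18:0/0:0),LysoPC,C26H54NO7P,M+K,[LPC 18:0 + K]+,marker,562.34,0.008,1.0,562.3278,562.3278,0.0,1.170,240.1
DG(16:0/18:0),DG,C37H72O5,M+H-H2O,[DG 34:0-H2O]+,marker,579.55,0.010,2.2,579.5347,579.5345,-0.3,1.283,263.1
DG(16:0/18:0),DG,C37H72O5,M+Na,[DG 34:0 + Na]+,marker,619.55,0.004,1.7,619.5272,619.5267,-0.8,1.278,261.6
Cer(d18:1/24:0),Cer,C42H83NO3,M+H-H2O,[Cer d42:1-H2O]+,marker,632.66,0.007,0.8,632.6340,632.6337,-0.5,1.355,277.3
HexCer(d34:1),HexCer,C40H77NO8,M+Na,[HexCer d34:1 + Na]+,marker,722.57,0.002,0.7,722.5541,722.5538,-0.4,1.368,279.2
PC(16:0/16:0),PC,C40H80NO8P,M+H,[PC 32:0]+,marker,734.59,0.008,0.8,734.5694,734.5696,0.3,1.386,282.8
SM(d18:1/16:0),SM,C39H79N2O6P,M+K,[SM 34:1 + K]+,marker,741.55,0.003,0.4,741.5307,741.5308,0.1,1.402,286.0
PC(14:0/16:0),PC,C38H76NO8P,M+K,[PC 30:0 + K]+,marker,744.52,0.008,0.6,744.4940,744.4941,0.1,1.378,281.1
PC(16:0/16:0),PC,C40H80NO8P,M+Na,[PC 32:0 + Na]+,marker,756.57,0.009,0.6,756.5513,756.5516,0.4,1.412,287.9
PC(16:0/16:0),PC,C40H80NO8P,M+K,[PC 32:0 + K]+,marker,772.55,0.001,0.9,772.5253,772.5254,0.1,1.407,286.8
PC(16:0/18:0),PC,C42H84NO8P,M+K,[PC 34:0 + K]+,marker,800.57,0.003,0.7,800.5566,800.5571,0.6,1.438,292.9
TG(48:0),TG,C51H98O6,M+Na,[TG 48:0 + Na]+,marker,829.74,0.002,1.7,829.7256,829.7255,-0.1,1.524,310.3
TG(50:0),TG,C53H102O6,M+Na,[TG 50:0 + Na]+,marker,857.77,0.005,1.6,857.7569,857.7577,0.9,1.545,314.4
PC(34:1),PC,C42H82NO8P,M+H,[PC 34:1 + H]+,calibrant,,,,,,,,
PC(34:1),PC,C42H82NO8P,M+Na,[PC 34:1 + Na]+,calibrant,,,,,,,,
PC(34:1),PC,C42H82NO8P,M+K,[PC 34:1 + K]+,calibrant,,,,,,,,
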