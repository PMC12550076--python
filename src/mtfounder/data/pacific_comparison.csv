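region,lat,lon,n,genetic_age,genetic_lo,genetic_hi,c14_older,c14_younger,evidence_class,source
Wallacea,-3.0,128.0,32,4300,2890,5740,3740,3020,red-slipped,Cochrane et al.
PNG Central Lowlands,-5.5,143.0,80,3550,2600,4510,,,,
PNG North Coast,-3.6,143.6,15,6450,3410,9550,3300,2700,Lapita,Terrell and Schechter
PNG Southeast Coast,-10.3,149.0,9,3460,1900,5030,3480,3060,frontier-Lapita,Shaw et al.
PNG Southeast Coast,-10.3,149.0,9,3460,1900,5030,2900,2500,Lapita,David et al.
New Ireland,-3.3,152.2,26,7270,4350,10250,3580,3180,Lapita,Spriggs
Bougainville,-6.2,155.3,121,4820,3130,6530,,,,
Solomon Islands,-9.0,160.0,555,3700,2960,4450,4080,3150,frontier-Lapita,Shaw et al. (Nissan)
Solomon Islands,-9.0,160.0,555,3700,2960,4450,3185,2639,Lapita,Sheppard et al.
Micronesia,7.0,158.2,33,3900,1600,6230,,,,
Vanuatu,-16.5,168.0,103,3450,2490,4410,3430,3030,Lapita,Denham et al.
Fiji,-17.8,178.0,45,2590,1610,3570,3050,2950,Lapita,Clark & Anderson
Futuna,-14.3,181.9,42,3270,1630,4930,2300,2000,first-settlement,Kirch
Tuvalu,-8.5,179.2,43,2460,1310,3630,1070,770,first-settlement,Dickinson et al.
Samoa,-13.8,188.0,45,2880,1980,3770,2900,2600,Lapita,Cochrane et al.
Tonga,-21.2,184.8,47,2530,1680,3380,2846,2830,Lapita,Burley et al.
Niue,-19.05,190.1,21,610,0,1250,2000,1600,first-settlement,Walter and Anderson
Cook Islands,-21.2,200.2,70,1510,850,2170,1150,725,first-settlement,Sear et al.
Aotearoa/New Zealand,-41.0,174.0,22,2060,770,3370,700,675,first-settlement,Bunbury et al.
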