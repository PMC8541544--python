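# CIE 1931 2-degree standard observer, 5 nm tabulation of the
# multi-lobe Gaussian analytic representation (Wyman, Sloan & Shirley 2013),
# renormalised to exactly equal integrals (equal-energy white at x=y=1/3).
wavelength_nm,xbar,ybar,zbar
380,0.00019939,0.00024903,0.00676522
385,0.00063732,0.00038034,0.01196855
390,0.00184767,0.00057431,0.02062269
395,0.00485830,0.00085742,0.03517447
400,0.01158609,0.00126561,0.06096598
405,0.02505991,0.00184703,0.10988131
410,0.04915972,0.00266508,0.20468770
415,0.08746279,0.00380199,0.37774552
420,0.14112884,0.00536260,0.65403452
425,0.20652659,0.00747832,1.01810271
430,0.27408292,0.01031090,1.39013571
435,0.32982759,0.01405572,1.64902568
440,0.35982249,0.01894411,1.73907629
445,0.35971870,0.02524423,1.78141238
450,0.34489258,0.03326003,1.78659164
455,0.31827829,0.04332857,1.75190049
460,0.28200799,0.05581721,1.67624451
465,0.23891470,0.07112605,1.52320600
470,0.19219974,0.08970813,1.29881104
475,0.14514469,0.11212906,1.04785291
480,0.10089836,0.13919235,0.81255423
485,0.06232427,0.17213642,0.61749251
490,0.03187140,0.21284099,0.46768839
495,0.01144114,0.26386107,0.35605427
500,0.00226104,0.32800106,0.27220720
505,0.00434969,0.40719623,0.20763847
510,0.01660036,0.50081987,0.15691926
515,0.03869561,0.60411700,0.11689583
520,0.07028264,0.70788615,0.08559404
525,0.11099395,0.80026191,0.06152343
530,0.16046055,0.87034714,0.04338767
535,0.21827946,0.91855576,0.03001543
540,0.28394047,0.95581349,0.02036821
545,0.35672479,0.98180349,0.01355768
550,0.43559461,0.99641840,0.00885198
555,0.51909689,1.00000000,0.00566915
560,0.60530441,0.99323003,0.00356138
565,0.69181289,0.97701098,0.00219452
570,0.77580480,0.95226559,0.00132643
575,0.85418028,0.91788614,0.00078642
580,0.92374533,0.87416030,0.00045734
585,0.98143812,0.82248166,0.00026089
590,1.02456849,0.76439528,0.00014598
595,1.05104246,0.70155613,0.00008012
600,1.05953795,0.63567888,0.00004313
605,1.04478444,0.56847827,0.00002278
610,1.00376773,0.50160268,0.00001180
615,0.93959128,0.43656643,0.00000600
620,0.85693005,0.37468798,0.00000299
625,0.76147058,0.31704060,0.00000146
630,0.65926888,0.26442107,0.00000070
635,0.55612689,0.21733884,0.00000033
640,0.45707468,0.17602557,0.00000015
645,0.36601797,0.14046241,0.00000007
650,0.28557465,0.11042048,0.00000003
655,0.21708955,0.08550909,0.00000001
660,0.16079043,0.06522641,0.00000001
665,0.11603352,0.04900771,0.00000000
670,0.08158471,0.03626779,0.00000000
675,0.05589026,0.02643524,0.00000000
680,0.03730486,0.01897769,0.00000000
685,0.02426034,0.01341825,0.00000000
690,0.01537199,0.00934410,0.00000000
695,0.00948999,0.00640863,0.00000000
700,0.00570825,0.00432889,0.00000000
705,0.00334536,0.00287986,0.00000000
710,0.00191022,0.00188690,0.00000000
715,0.00106274,0.00121761,0.00000000
720,0.00057607,0.00077383,0.00000000
725,0.00030424,0.00048436,0.00000000
730,0.00015656,0.00029859,0.00000000
735,0.00007849,0.00018128,0.00000000
740,0.00003834,0.00010840,0.00000000
745,0.00001825,0.00006384,0.00000000
750,0.00000846,0.00003702,0.00000000
755,0.00000382,0.00002115,0.00000000
760,0.00000168,0.00001190,0.00000000
765,0.00000072,0.00000659,0.00000000
770,0.00000030,0.00000360,0.00000000
775,0.00000012,0.00000193,0.00000000
780,0.00000005,0.00000102,0.00000000
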