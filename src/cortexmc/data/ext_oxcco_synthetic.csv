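# synthetic analytic spectrum: oxidized cytochrome-c-oxidase molar extinction, M^-1 cm^-1
wavelength_nm,value
400,29061.1
402,37147.1
404,46412.4
406,56666.3
408,67595.8
410,78771.2
412,89667.2
414,99699.7
416,108276
418,114852
420,118988
422,120400
424,118988
426,114852
428,108276
430,99699.7
432,89667.2
434,78771.2
436,67595.8
438,56666.3
440,46412.4
442,37147.1
444,29061.1
446,22231.4
448,16640.2
450,12198.4
452,8770.99
454,6200.3
456,4325.05
458,2993.96
460,2074.19
462,1455.29
464,1049.65
466,790.604
468,629.403
470,531.637
472,473.853
474,440.581
476,421.935
478,411.797
480,406.492
482,403.88
484,402.76
486,402.48
488,402.71
490,403.298
492,404.195
494,405.409
496,406.988
498,409.008
500,411.564
502,414.78
504,418.801
506,423.8
508,429.982
510,437.584
512,446.88
514,458.186
516,471.858
518,488.299
520,507.959
522,531.332
524,558.961
526,591.434
528,629.376
530,673.451
532,724.346
534,782.766
536,849.422
538,925.011
540,1010.21
542,1105.63
544,1211.83
546,1329.28
548,1458.32
550,1599.17
552,1751.85
554,1916.24
556,2091.99
558,2278.51
560,2475
562,2680.4
564,2893.4
566,3112.46
568,3335.77
570,3561.33
572,3786.93
574,4010.22
576,4228.68
578,4439.76
580,4640.85
582,4829.37
584,5002.82
586,5158.81
588,5295.18
590,5409.96
592,5501.49
594,5568.44
596,5609.84
598,5625.08
600,5613.98
602,5576.74
604,5513.99
606,5426.71
608,5316.27
610,5184.34
612,5032.89
614,4864.13
616,4680.45
618,4484.38
620,4278.51
622,4065.48
624,3847.86
626,3628.19
628,3408.84
630,3192.04
632,2979.82
634,2773.99
636,2576.13
638,2387.58
640,2209.4
642,2042.43
644,1887.28
646,1744.31
648,1613.68
650,1495.38
652,1389.22
654,1294.87
656,1211.9
658,1139.78
660,1077.9
662,1025.62
664,982.257
666,947.126
668,919.543
670,898.841
672,884.379
674,875.549
676,871.783
678,872.558
680,877.395
682,885.862
684,897.571
686,912.18
688,929.386
690,948.927
692,970.575
694,994.134
696,1019.44
698,1046.34
700,1074.73
702,1104.5
704,1135.57
706,1167.86
708,1201.3
710,1235.86
712,1271.47
714,1308.1
716,1345.71
718,1384.26
720,1423.72
722,1464.05
724,1505.22
726,1547.2
728,1589.94
730,1633.41
732,1677.58
734,1722.39
736,1767.81
738,1813.78
740,1860.27
742,1907.21
744,1954.56
746,2002.26
748,2050.25
750,2098.46
752,2146.85
754,2195.33
756,2243.85
758,2292.34
760,2340.72
762,2388.92
764,2436.87
766,2484.49
768,2531.71
770,2578.45
772,2624.63
774,2670.17
776,2715.01
778,2759.04
780,2802.21
782,2844.43
784,2885.62
786,2925.71
788,2964.63
790,3002.29
792,3038.62
794,3073.56
796,3107.04
798,3138.99
800,3169.35
802,3198.05
804,3225.04
806,3250.27
808,3273.67
810,3295.21
812,3314.83
814,3332.5
816,3348.19
818,3361.84
820,3373.45
822,3382.98
824,3390.42
826,3395.74
828,3398.93
830,3400
832,3398.93
834,3395.74
836,3390.42
838,3382.98
840,3373.45
842,3361.84
844,3348.19
846,3332.5
848,3314.83
850,3295.21
852,3273.67
854,3250.27
856,3225.04
858,3198.05
860,3169.35
862,3138.99
864,3107.04
866,3073.56
868,3038.62
870,3002.29
872,2964.63
874,2925.71
876,2885.62
878,2844.43
880,2802.21
882,2759.04
884,2715.01
886,2670.17
888,2624.63
890,2578.45
892,2531.71
894,2484.49
896,2436.87
898,2388.92
900,2340.72
902,2292.34
904,2243.85
906,2195.33
908,2146.85
910,2098.46
912,2050.24
914,2002.26
916,1954.56
918,1907.2
920,1860.26
922,1813.77
924,1767.78
926,1722.35
928,1677.52
930,1633.34
932,1589.83
934,1547.05
936,1505.01
938,1463.76
940,1423.32
942,1383.72
944,1344.98
946,1307.12
948,1270.16
950,1234.11
952,1198.99
954,1164.8
956,1131.55
958,1099.25
960,1067.9
962,1037.51
964,1008.06
966,979.565
968,952.011
970,925.392
972,899.702
974,874.93
976,851.065
978,828.095
980,806.006
982,784.783
984,764.41
986,744.87
988,726.146
990,708.219
992,691.071
994,674.681
996,659.03
998,644.097
1000,629.862
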