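# synthetic analytic spectrum: deoxyhemoglobin molar extinction, M^-1 cm^-1
wavelength_nm,value
400,223000
402,237257
404,252425
406,268563
408,285733
410,304000
412,319530
414,335854
416,353011
418,371045
420,390000
422,420221
424,452784
426,485538
428,518172
430,553000
432,531157
434,510177
436,476248
438,432076
440,392000
442,322149
444,264744
446,202763
448,144725
450,103300
452,96051.7
454,89312
456,83045.2
458,77218.2
460,71800
462,65394.6
464,59560.7
466,54247.2
468,49407.7
470,45000
472,42344.6
474,39845.8
476,37494.5
478,35282
480,33200
482,31368.8
484,29638.7
486,28003.9
488,26459.4
490,25000
492,24120.2
494,23271.4
496,22452.5
498,21662.3
500,20900
502,21115.5
504,21333.2
506,21553.2
508,21775.5
510,22000
512,22712.4
514,23447.8
516,24207
518,24990.8
520,25800
522,27422.6
524,29147.3
526,30980.5
528,32929
530,35000
532,37062.2
534,39246
536,41558.4
538,44007.1
540,46600
542,47663.1
544,48750.4
546,49862.5
548,51000
550,52247.1
552,53524.7
554,54833.6
556,55073.5
558,54230.3
560,53400
562,51626
564,49910.9
566,48252.8
568,46649.8
570,45100
572,43579.9
574,42111
576,40691.6
578,38973.9
580,37000
582,35068.6
584,33238.1
586,31503
588,29858.6
590,28300
592,24825.2
594,21777
596,19103.1
598,16757.6
600,14700
602,13453.9
604,12313.4
606,11269.6
608,10314.3
610,9440
612,8763.83
614,8136.09
616,7553.31
618,7012.28
620,6510
622,6211.93
624,5927.5
626,5656.1
628,5397.12
630,5150
632,4979.02
634,4813.71
636,4653.89
638,4499.38
640,4350
642,4222.77
644,4099.27
646,3979.37
648,3862.98
650,3750
652,3639.7
654,3532.64
656,3428.74
658,3327.88
660,3230
662,3136.78
664,3046.25
666,2958.33
668,2872.95
670,2790.04
672,2709.51
674,2631.31
676,2555.37
678,2481.62
680,2410
682,2340.68
684,2273.36
686,2207.97
688,2144.47
690,2082.79
692,2022.88
694,1964.7
696,1908.19
698,1853.31
700,1800
702,1763.91
704,1728.55
706,1693.89
708,1659.93
710,1626.65
712,1594.04
714,1562.08
716,1530.76
718,1500.07
720,1470
722,1456.45
724,1443.03
726,1429.73
728,1416.55
730,1403.5
732,1390.56
734,1377.74
736,1365.05
738,1352.47
740,1340
742,1353.72
744,1367.57
746,1381.57
748,1395.71
750,1410
752,1458.54
754,1508.75
756,1560.69
758,1614.42
760,1670
762,1641.01
764,1612.52
766,1584.53
768,1557.03
770,1530
772,1492.18
774,1455.29
776,1419.31
778,1384.22
780,1350
782,1286.26
784,1225.53
786,1167.66
788,1112.53
790,1060
792,992.283
794,928.893
796,869.552
798,814.001
800,762
802,756.633
804,751.304
806,746.012
808,740.758
810,735.541
812,730.36
814,725.216
816,720.108
818,715.036
820,710
822,707.974
824,705.954
826,703.94
828,701.931
830,699.929
832,697.931
834,695.94
836,693.954
838,691.974
840,690
842,690.4
844,690.799
846,691.199
848,691.6
850,692
852,694.471
854,696.95
856,699.438
858,701.936
860,704.442
862,706.957
864,709.481
866,712.014
868,714.556
870,717.107
872,719.667
874,722.237
876,724.815
878,727.403
880,730
882,733.139
884,736.291
886,739.456
888,742.635
890,745.828
892,749.035
894,752.255
896,755.49
898,758.738
900,762
902,763.781
904,765.566
906,767.356
908,769.15
910,770.947
912,772.75
914,774.556
916,776.366
918,778.181
920,780
922,781.977
924,783.96
926,785.947
928,787.939
930,789.937
932,791.939
934,793.947
936,795.959
938,797.977
940,800
942,793.787
944,787.623
946,781.506
948,775.437
950,769.415
952,763.44
954,757.511
956,751.629
958,745.792
960,740
962,730.466
964,721.054
966,711.764
968,702.594
970,693.542
972,684.606
974,675.785
976,667.079
978,658.484
980,650
982,639.232
984,628.642
986,618.227
988,607.985
990,597.913
992,588.008
994,578.266
996,568.686
998,559.265
1000,550
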