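# synthetic analytic spectrum: oxyhemoglobin molar extinction, M^-1 cm^-1
wavelength_nm,value
400,266000
402,316951
404,377661
406,450000
408,467458
410,485592
412,504431
414,524000
416,483246
418,445661
420,411000
422,333710
424,270954
426,220000
428,174614
430,138591
432,110000
434,98246.9
436,87749.6
438,78373.9
440,70000
442,68496.8
444,67025.9
446,65586.6
448,64178.2
450,62800
452,58619.2
454,54716.7
456,51074
458,47673.8
460,44500
462,41967.7
464,39579.6
466,37327.3
468,35203.2
470,33200
472,31760.5
474,30383.3
476,29065.9
478,27805.6
480,26600
482,25837.5
484,25096.9
486,24377.5
488,23678.7
490,23000
492,22563.8
494,22135.8
496,21716
498,21304.1
500,20900
502,20716.8
504,20535.2
506,20355.3
508,20176.8
510,20000
512,20777.2
514,21584.6
516,22423.4
518,23294.8
520,24200
522,26623.5
524,29289.7
526,32222.9
528,35449.9
530,39000
532,42022.1
534,45278.4
536,48373.5
538,51242.2
540,54281
542,57500
544,54882.7
546,52384.5
548,50000
550,46229.2
552,42742.9
554,39519.4
556,36852.8
558,34661.2
560,32600
562,33539.6
564,34506.3
566,36787.8
568,40642
570,44900
572,49795.8
574,55225.5
576,61247.2
578,62195.8
580,57831.5
582,53773.3
584,50000
586,40514.2
588,32828
590,26600
592,17442.5
594,11437.6
596,7500
598,4898.98
600,3200
602,2651.56
604,2197.12
606,1888.18
608,1682.93
610,1500
612,1366.73
614,1245.3
616,1134.66
618,1033.85
620,942
622,863.588
624,791.703
626,725.802
628,665.387
630,610
632,571.937
634,536.249
636,502.788
638,471.415
640,442
642,426.096
644,410.764
646,395.984
648,381.736
650,368
652,357.632
654,347.556
656,337.764
658,328.248
660,319
662,315.974
664,312.977
666,310.008
668,307.067
670,304.155
672,301.269
674,298.412
676,295.581
678,292.777
680,290
682,290
684,290
686,290
688,290
690,290
692,290
694,290
696,290
698,290
700,290
702,294.126
704,298.31
706,302.554
708,306.858
710,311.223
712,315.651
714,320.141
716,324.696
718,329.315
720,334
722,343.8
724,353.887
726,364.27
728,374.957
730,385.959
732,397.283
734,408.939
736,420.937
738,433.287
740,446
742,458.344
744,471.029
746,484.065
748,497.462
750,511.23
752,525.379
754,539.919
756,554.862
758,570.219
760,586
762,597.357
764,608.933
766,620.734
768,632.764
770,645.027
772,657.528
774,670.271
776,683.26
778,696.502
780,710
782,719.949
784,730.037
786,740.266
788,750.639
790,761.157
792,771.822
794,782.637
796,793.604
798,804.724
800,816
802,825.488
804,835.086
806,844.796
808,854.618
810,864.555
812,874.608
814,884.777
816,895.065
818,905.472
820,916
822,926.085
824,936.282
826,946.59
828,957.013
830,967.549
832,978.202
834,988.973
836,999.861
838,1010.87
840,1022
842,1028.79
844,1035.63
846,1042.52
848,1049.44
850,1056.42
852,1063.44
854,1070.51
856,1077.63
858,1084.79
860,1092
862,1098.05
864,1104.13
866,1110.24
868,1116.39
870,1122.57
872,1128.79
874,1135.04
876,1141.32
878,1147.64
880,1154
882,1158.33
884,1162.67
886,1167.03
888,1171.4
890,1175.79
892,1180.2
894,1184.63
896,1189.07
898,1193.53
900,1198
902,1201.55
904,1205.11
906,1208.69
908,1212.27
910,1215.87
912,1219.47
914,1223.09
916,1226.71
918,1230.35
920,1234
922,1231.99
924,1229.97
926,1227.97
928,1225.96
930,1223.96
932,1221.96
934,1219.97
936,1217.97
938,1215.99
940,1214
942,1211.99
944,1209.97
946,1207.97
948,1205.96
950,1203.96
952,1201.96
954,1199.97
956,1197.97
958,1195.99
960,1194
962,1187.44
964,1180.92
966,1174.43
968,1167.98
970,1161.56
972,1155.18
974,1148.83
976,1142.52
978,1136.24
980,1130
982,1122.58
984,1115.22
986,1107.9
988,1100.63
990,1093.41
992,1086.23
994,1079.1
996,1072.02
998,1064.99
1000,1058
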