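# synthetic analytic spectrum: oxidized cytochrome c molar extinction, M^-1 cm^-1
wavelength_nm,value
400,66451.5
402,77061.8
404,86477.6
406,93902.3
408,98660.7
410,100300
412,98660.7
414,93902.3
416,86477.6
418,77061.8
420,66451.5
422,55454
424,44789.5
426,35020.1
428,26514.9
430,19449.6
432,13833.6
434,9553.68
436,6421.59
438,4218.07
440,2726.4
442,1754.11
444,1143.64
446,774.397
448,559.393
450,439.202
452,375.236
454,343.662
456,330.516
458,328.113
460,332.605
462,342.424
464,357.357
466,378.028
468,405.627
470,441.782
472,488.503
474,548.158
476,623.452
478,717.401
480,833.28
482,974.551
484,1144.76
486,1347.38
488,1585.69
490,1862.51
492,2180.04
494,2539.59
496,2941.35
498,3384.2
500,3865.46
502,4380.79
504,4924.15
506,5487.71
508,6062.04
510,6636.28
512,7198.42
514,7735.69
516,8235.07
518,8683.72
520,9069.61
522,9381.98
524,9611.89
526,9752.62
528,9800
530,9752.62
532,9611.89
534,9381.98
536,9069.61
538,8683.72
540,8235.07
542,7735.69
544,7198.42
546,6636.28
548,6062.04
550,5487.71
552,4924.15
554,4380.79
556,3865.46
558,3384.2
560,2941.35
562,2539.59
564,2180.04
566,1862.51
568,1585.69
570,1347.38
572,1144.76
574,974.551
576,833.28
578,717.401
580,623.451
582,548.153
584,488.49
586,441.747
588,405.535
590,377.793
592,356.772
594,341.019
596,329.343
598,320.781
600,314.571
602,310.115
604,306.952
606,304.731
608,303.187
610,302.126
612,301.405
614,300.921
616,300.6
618,300.391
620,300.26
622,300.185
624,300.153
626,300.159
628,300.207
630,300.308
632,300.486
634,300.775
636,301.231
638,301.932
640,302.99
642,304.558
644,306.842
646,310.111
648,314.711
650,321.073
652,329.718
654,341.259
656,356.394
658,375.886
660,400.533
662,431.12
664,468.361
666,512.829
668,564.87
670,624.525
672,691.452
674,764.86
676,843.477
678,925.538
680,1008.83
682,1090.75
684,1168.47
686,1239.04
688,1299.61
690,1347.58
692,1380.83
694,1397.85
696,1397.85
698,1380.83
700,1347.58
702,1299.61
704,1239.04
706,1168.47
708,1090.75
710,1008.83
712,925.538
714,843.477
716,764.86
718,691.452
720,624.525
722,564.87
724,512.829
726,468.361
728,431.12
730,400.533
732,375.886
734,356.394
736,341.259
738,329.718
740,321.073
742,314.711
744,310.111
746,306.841
748,304.557
750,302.989
752,301.93
754,301.227
756,300.768
758,300.473
760,300.287
762,300.171
764,300.101
766,300.058
768,300.033
770,300.019
772,300.01
774,300.006
776,300.003
778,300.002
780,300.001
782,300
784,300
786,300
788,300
790,300
792,300
794,300
796,300
798,300
800,300
802,300
804,300
806,300
808,300
810,300
812,300
814,300
816,300
818,300
820,300
822,300
824,300
826,300
828,300
830,300
832,300
834,300
836,300
838,300
840,300
842,300
844,300
846,300
848,300
850,300
852,300
854,300
856,300
858,300
860,300
862,300
864,300
866,300
868,300
870,300
872,300
874,300
876,300
878,300
880,300
882,300
884,300
886,300
888,300
890,300
892,300
894,300
896,300
898,300
900,300
902,300
904,300
906,300
908,300
910,300
912,300
914,300
916,300
918,300
920,300
922,300
924,300
926,300
928,300
930,300
932,300
934,300
936,300
938,300
940,300
942,300
944,300
946,300
948,300
950,300
952,300
954,300
956,300
958,300
960,300
962,300
964,300
966,300
968,300
970,300
972,300
974,300
976,300
978,300
980,300
982,300
984,300
986,300
988,300
990,300
992,300
994,300
996,300
998,300
1000,300
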