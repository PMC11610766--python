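# synthetic analytic spectrum: oxidized cytochrome b molar extinction, M^-1 cm^-1
wavelength_nm,value
400,36011.8
402,45522.4
404,55996.9
406,67018.4
408,78031.3
410,88381.1
412,97374.7
414,104356
416,108783
418,110300
420,108783
422,104356
424,97374.7
426,88381.1
428,78031.3
430,67018.4
432,55997
434,45522.4
436,36011.9
438,27728.9
440,20790
442,15187.2
444,10820.2
446,7530.74
448,5133.9
450,3443.37
452,2288.54
454,1524.2
456,1033.97
458,729.346
460,546.145
462,439.824
464,380.741
466,349.96
468,335.879
470,331.709
472,333.695
474,339.938
476,349.648
478,362.688
480,379.318
482,400.054
484,425.591
486,456.767
488,494.549
490,540.021
492,594.378
494,658.915
496,735.021
498,824.154
500,927.823
502,1047.56
504,1184.88
506,1341.25
508,1518.02
510,1716.39
512,1937.36
514,2181.63
516,2449.58
518,2741.2
520,3056.03
522,3393.11
524,3750.93
526,4127.44
528,4519.97
530,4925.31
532,5339.68
534,5758.78
536,6177.84
538,6591.73
540,6995.04
542,7382.16
544,7747.48
546,8085.43
548,8390.7
550,8658.34
552,8883.89
554,9063.52
556,9194.12
558,9273.41
560,9300
562,9273.41
564,9194.12
566,9063.52
568,8883.89
570,8658.34
572,8390.7
574,8085.43
576,7747.48
578,7382.16
580,6995.04
582,6591.73
584,6177.84
586,5758.78
588,5339.68
590,4925.31
592,4519.97
594,4127.44
596,3750.93
598,3393.11
600,3056.03
602,2741.2
604,2449.58
606,2181.63
608,1937.36
610,1716.39
612,1518.02
614,1341.25
616,1184.88
618,1047.56
620,927.823
622,824.154
624,735.021
626,658.915
628,594.377
630,540.019
632,494.544
634,456.755
636,425.561
638,399.981
640,379.143
642,362.278
644,348.718
646,337.885
648,329.288
650,322.508
652,317.195
654,313.059
656,309.859
658,307.4
660,305.521
662,304.095
664,303.019
666,302.213
668,301.612
670,301.168
672,300.841
674,300.602
676,300.428
678,300.303
680,300.213
682,300.149
684,300.104
686,300.072
688,300.049
690,300.034
692,300.023
694,300.015
696,300.01
698,300.007
700,300.005
702,300.003
704,300.002
706,300.001
708,300.001
710,300.001
712,300
714,300
716,300
718,300
720,300
722,300
724,300
726,300
728,300
730,300
732,300
734,300
736,300
738,300
740,300
742,300
744,300
746,300
748,300
750,300
752,300
754,300
756,300
758,300
760,300
762,300
764,300
766,300
768,300
770,300
772,300
774,300
776,300
778,300
780,300
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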