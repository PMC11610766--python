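# synthetic analytic spectrum: reduced cytochrome-c-oxidase molar extinction, M^-1 cm^-1
wavelength_nm,value
400,504.656
402,671.873
404,957.206
406,1429.65
408,2188.53
410,3370.71
412,5156.14
414,7769.28
416,11473.8
418,16557.9
420,23307
422,31966
424,42689.9
426,55490.9
428,70189.1
430,86377.1
432,103410
434,120430
436,136425
438,150324
440,161113
442,167955
444,170300
446,167955
448,161113
450,150324
452,136425
454,120430
456,103410
458,86377.1
460,70189.1
462,55490.9
464,42689.9
466,31966
468,23307
470,16557.9
472,11473.8
474,7769.28
476,5156.14
478,3370.71
480,2188.53
482,1429.65
484,957.206
486,671.873
488,504.656
490,409.545
492,357.029
494,328.876
496,314.22
498,306.811
500,303.173
502,301.438
504,300.634
506,300.272
508,300.113
510,300.046
512,300.018
514,300.007
516,300.003
518,300.001
520,300
522,300
524,300
526,300
528,300
530,300
532,300
534,300
536,300
538,300
540,300
542,300
544,300
546,300.001
548,300.002
550,300.006
552,300.017
554,300.047
556,300.128
558,300.335
560,300.841
562,302.028
564,304.699
566,310.457
568,322.36
570,345.937
572,390.675
574,471.963
576,613.337
578,848.55
580,1222.68
582,1791.11
584,2615.26
586,3753.96
588,5250.67
590,7117.7
592,9320.7
594,11767.6
596,14306.5
598,16736.8
600,18832.4
602,20375.9
604,21195.3
606,21195.3
608,20375.9
610,18832.4
612,16736.8
614,14306.5
616,11767.6
618,9320.7
620,7117.7
622,5250.67
624,3753.96
626,2615.26
628,1791.11
630,1222.68
632,848.55
634,613.337
636,471.963
638,390.675
640,345.937
642,322.36
644,310.457
646,304.699
648,302.028
650,300.841
652,300.335
654,300.128
656,300.047
658,300.017
660,300.006
662,300.002
664,300.001
666,300
668,300
670,300
672,300
674,300
676,300
678,300
680,300
682,300
684,300
686,300
688,300
690,300
692,300
694,300
696,300
698,300
700,300
702,300
704,300
706,300
708,300
710,300
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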