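# synthetic analytic spectrum: reduced cytochrome b molar extinction, M^-1 cm^-1
wavelength_nm,value
400,1090.31
402,1977.44
404,3577.55
406,6308.87
408,10716.6
410,17432.2
412,27075.7
414,40096.4
416,56571.5
418,76012.3
420,97244.9
422,118439
424,137320
426,151554
428,159215
430,159215
432,151554
434,137320
436,118439
438,97244.9
440,76012.3
442,56571.5
444,40096.4
446,27075.7
448,17432.2
450,10716.6
452,6308.87
454,3577.55
456,1977.44
458,1090.31
460,624.465
462,392.618
464,283.196
466,234.203
468,213.384
470,204.985
472,201.768
474,200.598
476,200.197
478,200.073
480,200.058
482,200.114
484,200.281
486,200.688
488,201.625
490,203.69
492,208.05
494,216.872
496,233.976
498,265.736
500,322.199
502,418.252
504,574.522
506,817.482
508,1178.14
510,1688.69
512,2376.89
514,3258.41
516,4328.42
518,5554.27
520,6871.84
522,8187.64
524,9387.98
526,10354.3
528,10982.4
530,11200.8
532,10985
534,10363.3
536,9415.24
538,8263.28
540,7065.25
542,6010.03
544,5318.19
546,5239.39
548,6030.94
550,7900.48
552,10910.2
554,14869.6
556,19273.9
558,23351.1
560,26242.3
562,27265.7
564,26154.1
566,23149.7
568,18907.4
570,14255.8
572,9933.72
574,6412.48
576,3854.33
578,2181.09
580,1189.81
582,655.772
584,393.416
586,275.646
588,227.266
590,209.058
592,202.773
594,200.782
596,200.203
598,200.049
600,200.011
602,200.002
604,200
606,200
608,200
610,200
612,200
614,200
616,200
618,200
620,200
622,200
624,200
626,200
628,200
630,200
632,200
634,200
636,200
638,200
640,200
642,200
644,200
646,200
648,200
650,200
652,200
654,200
656,200
658,200
660,200
662,200
664,200
666,200
668,200
670,200
672,200
674,200
676,200
678,200
680,200
682,200
684,200
686,200
688,200
690,200
692,200
694,200
696,200
698,200
700,200
702,200
704,200
706,200
708,200
710,200
712,200
714,200
716,200
718,200
720,200
722,200
724,200
726,200
728,200
730,200
732,200
734,200
736,200
738,200
740,200
742,200
744,200
746,200
748,200
750,200
752,200
754,200
756,200
758,200
760,200
762,200
764,200
766,200
768,200
770,200
772,200
774,200
776,200
778,200
780,200
782,200
784,200
786,200
788,200
790,200
792,200
794,200
796,200
798,200
800,200
802,200
804,200
806,200
808,200
810,200
812,200
814,200
816,200
818,200
820,200
822,200
824,200
826,200
828,200
830,200
832,200
834,200
836,200
838,200
840,200
842,200
844,200
846,200
848,200
850,200
852,200
854,200
856,200
858,200
860,200
862,200
864,200
866,200
868,200
870,200
872,200
874,200
876,200
878,200
880,200
882,200
884,200
886,200
888,200
890,200
892,200
894,200
896,200
898,200
900,200
902,200
904,200
906,200
908,200
910,200
912,200
914,200
916,200
918,200
920,200
922,200
924,200
926,200
928,200
930,200
932,200
934,200
936,200
938,200
940,200
942,200
944,200
946,200
948,200
950,200
952,200
954,200
956,200
958,200
960,200
962,200
964,200
966,200
968,200
970,200
972,200
974,200
976,200
978,200
980,200
982,200
984,200
986,200
988,200
990,200
992,200
994,200
996,200
998,200
1000,200
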