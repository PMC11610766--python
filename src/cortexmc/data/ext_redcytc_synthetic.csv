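# synthetic analytic spectrum: reduced cytochrome c molar extinction, M^-1 cm^-1
wavelength_nm,value
400,25940.5
402,37479.3
404,51589
406,67625.9
408,84404.8
410,100292
412,113444
414,122151
416,125200
418,122151
420,113444
422,100292
424,84404.8
426,67625.9
428,51589
430,37479.3
432,25940.5
434,17116.9
436,10782.2
438,6500.69
440,3770.69
442,2126.06
444,1188.87
446,683.24
448,424.771
450,299.511
452,241.933
454,216.819
456,206.421
458,202.333
460,200.807
462,200.266
464,200.083
466,200.025
468,200.007
470,200.004
472,200.006
474,200.018
476,200.056
478,200.166
480,200.467
482,201.255
484,203.207
486,207.8
488,218.058
490,239.794
492,283.467
494,366.635
496,516.645
498,772.707
500,1185.93
502,1815.52
504,2719.6
506,3940.28
508,5484.83
510,7307.4
512,9297.96
514,11284.9
516,13055
518,14389.4
520,15107.8
522,15108.2
524,14391.7
526,13064.3
528,11318.6
530,9406.21
532,7618.45
534,6284.66
536,5780.68
538,6508.99
540,8797.38
542,12697.1
544,17755.6
546,22937.3
548,26853.5
550,28283.5
552,26726.7
554,22638.7
556,17190.7
558,11714.4
560,7183.12
562,3989.86
564,2040.56
566,999.89
568,511.07
570,308.251
572,233.71
574,209.393
576,202.342
578,200.523
580,200.104
582,200.019
584,200.003
586,200
588,200
590,200
592,200
594,200
596,200
598,200
600,200
602,200
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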