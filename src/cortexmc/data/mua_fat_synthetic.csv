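# synthetic analytic spectrum: pure lipid absorption coefficient, cm^-1
wavelength_nm,value
400,0.013
402,0.0126445
404,0.0122987
406,0.0119624
408,0.0116353
410,0.0113172
412,0.0110077
414,0.0107067
416,0.0104139
418,0.0101291
420,0.00985216
422,0.00958275
424,0.00932071
426,0.00906583
428,0.00881793
430,0.0085768
432,0.00834227
434,0.00811415
436,0.00789227
438,0.00767645
440,0.00746654
442,0.00726237
444,0.00706378
446,0.00687062
448,0.00668274
450,0.0065
452,0.00640509
454,0.00631157
456,0.00621941
458,0.0061286
460,0.00603911
462,0.00595093
464,0.00586404
466,0.00577842
468,0.00569405
470,0.00561091
472,0.00552898
474,0.00544825
476,0.0053687
478,0.00529031
480,0.00521306
482,0.00513694
484,0.00506194
486,0.00498803
488,0.00491519
490,0.00484343
492,0.00477271
494,0.00470302
496,0.00463435
498,0.00456668
500,0.0045
502,0.00445499
504,0.00441043
506,0.00436632
508,0.00432264
510,0.00427941
512,0.0042366
514,0.00419423
516,0.00415228
518,0.00411074
520,0.00406963
522,0.00402892
524,0.00398862
526,0.00394873
528,0.00390923
530,0.00387013
532,0.00383142
534,0.0037931
536,0.00375516
538,0.0037176
540,0.00368042
542,0.0036436
544,0.00360716
546,0.00357108
548,0.00353536
550,0.0035
552,0.00347849
554,0.0034571
556,0.00343585
558,0.00341473
560,0.00339374
562,0.00337288
564,0.00335215
566,0.00333154
568,0.00331106
570,0.00329071
572,0.00327048
574,0.00325038
576,0.0032304
578,0.00321054
580,0.0031908
582,0.00317119
584,0.0031517
586,0.00313232
588,0.00311307
590,0.00309393
592,0.00307491
594,0.00305601
596,0.00303723
598,0.00301856
600,0.003
602,0.00299173
604,0.00298349
606,0.00297527
608,0.00296707
610,0.00295889
612,0.00295073
614,0.0029426
616,0.00293449
618,0.00292641
620,0.00291834
622,0.0029103
624,0.00290228
626,0.00289428
628,0.0028863
630,0.00287835
632,0.00287042
634,0.00286251
636,0.00285462
638,0.00284675
640,0.0028389
642,0.00283108
644,0.00282328
646,0.0028155
648,0.00280774
650,0.0028
652,0.00280774
654,0.0028155
656,0.00282328
658,0.00283108
660,0.0028389
662,0.00284675
664,0.00285462
666,0.00286251
668,0.00287042
670,0.00287835
672,0.0028863
674,0.00289428
676,0.00290228
678,0.0029103
680,0.00291834
682,0.00292641
684,0.00293449
686,0.0029426
688,0.00295073
690,0.00295889
692,0.00296707
694,0.00297527
696,0.00298349
698,0.00299173
700,0.003
702,0.00303472
704,0.00306984
706,0.00310537
708,0.00314131
710,0.00317767
712,0.00321445
714,0.00325165
716,0.00328929
718,0.00332736
720,0.00336587
722,0.00340482
724,0.00344423
726,0.00348409
728,0.00352441
730,0.0035652
732,0.00360647
734,0.00364821
736,0.00369043
738,0.00373314
740,0.00377635
742,0.00382006
744,0.00386427
746,0.00390899
748,0.00395423
750,0.004
752,0.00440789
754,0.00485737
756,0.00535269
758,0.00589851
760,0.0065
762,0.00616772
764,0.00585243
766,0.00555325
768,0.00526937
770,0.005
772,0.004965
774,0.00493025
776,0.00489574
778,0.00486147
780,0.00482745
782,0.00479366
784,0.0047601
786,0.00472679
788,0.0046937
790,0.00466085
792,0.00462823
794,0.00459583
796,0.00456366
798,0.00453172
800,0.0045
802,0.00453627
804,0.00457282
806,0.00460968
808,0.00464683
810,0.00468428
812,0.00472203
814,0.00476008
816,0.00479845
818,0.00483712
820,0.0048761
822,0.0049154
824,0.00495501
826,0.00499494
828,0.0050352
830,0.00507578
832,0.00511668
834,0.00515792
836,0.00519949
838,0.00524139
840,0.00528363
842,0.00532621
844,0.00536914
846,0.00541241
848,0.00545603
850,0.0055
852,0.00559661
854,0.00569491
856,0.00579495
858,0.00589674
860,0.00600031
862,0.00610571
864,0.00621296
866,0.00632209
868,0.00643314
870,0.00654614
872,0.00666112
874,0.00677813
876,0.00689719
878,0.00701834
880,0.00714161
882,0.00726706
884,0.00739471
886,0.0075246
888,0.00765677
890,0.00779126
892,0.00792811
894,0.00806737
896,0.00820908
898,0.00835327
900,0.0085
902,0.00934801
904,0.0102806
906,0.0113063
908,0.0124343
910,0.0136748
912,0.0150391
914,0.0165395
916,0.0181895
918,0.0200043
920,0.022
922,0.029477
924,0.0394951
926,0.052918
928,0.0709028
930,0.095
932,0.0866581
934,0.0790487
936,0.0721075
938,0.0657757
940,0.06
942,0.055982
944,0.052233
946,0.0487351
948,0.0454715
950,0.0424264
952,0.0395852
954,0.0369343
956,0.034461
958,0.0321532
960,0.03
962,0.0297937
964,0.0295889
966,0.0293854
968,0.0291834
970,0.0289828
972,0.0287835
974,0.0285856
976,0.028389
978,0.0281938
980,0.028
982,0.0283764
984,0.0287579
986,0.0291444
988,0.0295362
990,0.0299333
992,0.0303356
994,0.0307434
996,0.0311567
998,0.0315755
1000,0.032
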