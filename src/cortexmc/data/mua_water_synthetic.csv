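# synthetic analytic spectrum: pure water absorption coefficient, cm^-1
wavelength_nm,value
400,0.00058
402,0.00056671
404,0.000553725
406,0.000541037
408,0.00052864
410,0.000516527
412,0.000504691
414,0.000493127
416,0.000481828
418,0.000470787
420,0.00046
422,0.000448861
424,0.000437993
426,0.000427387
428,0.000417038
430,0.00040694
432,0.000397086
434,0.000387471
436,0.000378089
438,0.000368933
440,0.00036
442,0.000354657
444,0.000349393
446,0.000344207
448,0.000339099
450,0.000334066
452,0.000329108
454,0.000324223
456,0.000319411
458,0.00031467
460,0.00031
462,0.00031
464,0.00031
466,0.00031
468,0.00031
470,0.00031
472,0.00031
474,0.00031
476,0.00031
478,0.00031
480,0.00031
482,0.000313785
484,0.000317616
486,0.000321495
488,0.00032542
490,0.000329393
492,0.000333415
494,0.000337486
496,0.000341607
498,0.000345778
500,0.00035
502,0.000361231
504,0.000372823
506,0.000384787
508,0.000397134
510,0.000409878
512,0.000423031
514,0.000436606
516,0.000450616
518,0.000465076
520,0.00048
522,0.000498456
524,0.000517622
526,0.000537525
528,0.000558192
530,0.000579655
532,0.000601943
534,0.000625088
536,0.000649123
538,0.000674081
540,0.0007
542,0.000717815
544,0.000736083
546,0.000754816
548,0.000774026
550,0.000793725
552,0.000813926
554,0.00083464
556,0.000855881
558,0.000877664
560,0.0009
562,0.000926267
564,0.000953301
566,0.000981125
568,0.00100976
570,0.00103923
572,0.00106956
574,0.00110078
576,0.00113291
578,0.00116597
580,0.0012
582,0.00128067
584,0.00136675
586,0.00145863
588,0.00155668
590,0.00166132
592,0.001773
594,0.00189219
596,0.00201938
598,0.00215513
600,0.0023
602,0.00234569
604,0.00239229
606,0.00243981
608,0.00248828
610,0.00253772
612,0.00258813
614,0.00263954
616,0.00269198
618,0.00274546
620,0.0028
622,0.00282864
624,0.00285758
626,0.00288682
628,0.00291635
630,0.00294618
632,0.00297632
634,0.00300677
636,0.00303753
638,0.00306861
640,0.0031
642,0.0031467
644,0.00319411
646,0.00324223
648,0.00329108
650,0.00334066
652,0.00339099
654,0.00344207
656,0.00349393
658,0.00354657
660,0.0036
662,0.00368123
664,0.0037643
666,0.00384924
668,0.0039361
670,0.00402492
672,0.00411575
674,0.00420862
676,0.00430359
678,0.0044007
680,0.0045
682,0.00463134
684,0.00476651
686,0.00490562
688,0.0050488
690,0.00519615
692,0.00534781
694,0.00550389
696,0.00566453
698,0.00582985
700,0.006
702,0.00640333
704,0.00683377
706,0.00729315
708,0.00778341
710,0.00830662
712,0.00886501
714,0.00946093
716,0.0100969
718,0.0107756
720,0.0115
722,0.0123519
724,0.013267
726,0.0142498
728,0.0153054
730,0.0164393
732,0.0176571
734,0.0189652
736,0.0203701
738,0.0218792
740,0.0235
742,0.0240168
744,0.0245449
746,0.0250846
748,0.0256363
750,0.0262
752,0.0260789
754,0.0259583
756,0.0258383
758,0.0257189
760,0.0256
762,0.0253926
764,0.0251869
766,0.0249828
768,0.0247804
770,0.0245797
772,0.0243805
774,0.024183
776,0.0239871
778,0.0237928
780,0.0236
782,0.0232813
784,0.0229669
786,0.0226568
788,0.0223509
790,0.022049
792,0.0217513
794,0.0214576
796,0.0211678
798,0.020882
800,0.0206
802,0.0211094
804,0.0216314
806,0.0221663
808,0.0227145
810,0.0232762
812,0.0238518
814,0.0244416
816,0.025046
818,0.0256653
820,0.0263
822,0.0276509
824,0.0290712
826,0.0305644
828,0.0321343
830,0.0337849
832,0.0355203
834,0.0373447
836,0.039263
838,0.0412797
840,0.0434
842,0.0441491
844,0.0449111
846,0.0456862
848,0.0464747
850,0.0472768
852,0.0480928
854,0.0489229
856,0.0497673
858,0.0506262
860,0.0515
862,0.0521158
864,0.0527389
866,0.0533695
868,0.0540077
870,0.0546535
872,0.0553069
874,0.0559683
876,0.0566375
878,0.0573147
880,0.058
882,0.0589213
884,0.0598572
886,0.060808
888,0.0617739
890,0.0627551
892,0.0637519
894,0.0647645
896,0.0657933
898,0.0668383
900,0.0679
902,0.0712561
904,0.0747781
906,0.0784742
908,0.0823529
910,0.0864234
912,0.090695
914,0.0951778
916,0.0998822
918,0.104819
920,0.11
922,0.1202
924,0.131346
926,0.143525
928,0.156834
930,0.171377
932,0.187268
934,0.204633
936,0.223608
938,0.244343
940,0.267
942,0.279373
944,0.29232
946,0.305867
948,0.320042
950,0.334873
952,0.350392
954,0.36663
956,0.38362
958,0.401398
960,0.42
962,0.425836
964,0.431752
966,0.437751
968,0.443833
970,0.45
972,0.445927
974,0.441891
976,0.437891
978,0.433928
980,0.43
982,0.422427
984,0.414988
986,0.407679
988,0.4005
990,0.393446
992,0.386517
994,0.37971
996,0.373023
998,0.366454
1000,0.36
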