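# synthetic parametric stand-in spectrum; see stormsim.spectral
wavelength_nm,value
400,3.73011e-05
401,4.07154e-05
402,4.44172e-05
403,4.84279e-05
404,5.2771e-05
405,5.74709e-05
406,6.25539e-05
407,6.8048e-05
408,7.39826e-05
409,8.03892e-05
410,8.73011e-05
411,9.47535e-05
412,0.000102784
413,0.000111432
414,0.000120738
415,0.000130748
416,0.000141508
417,0.000153066
418,0.000165475
419,0.000178788
420,0.000193062
421,0.000208359
422,0.000224739
423,0.00024227
424,0.000261021
425,0.000281063
426,0.000302473
427,0.00032533
428,0.000349715
429,0.000375715
430,0.000403419
431,0.00043292
432,0.000464316
433,0.000497706
434,0.000533195
435,0.00057089
436,0.000610905
437,0.000653353
438,0.000698355
439,0.000746034
440,0.000796516
441,0.000849932
442,0.000906416
443,0.000966107
444,0.00102914
445,0.00109567
446,0.00116584
447,0.0012398
448,0.00131771
449,0.00139971
450,0.00148598
451,0.00157667
452,0.00167195
453,0.00177198
454,0.00187692
455,0.00198696
456,0.00210226
457,0.00222299
458,0.00234932
459,0.00248142
460,0.00261946
461,0.00276361
462,0.00291405
463,0.00307093
464,0.00323443
465,0.0034047
466,0.0035819
467,0.00376619
468,0.00395771
469,0.00415662
470,0.00436305
471,0.00457714
472,0.00479901
473,0.00502879
474,0.00526658
475,0.00551249
476,0.00576661
477,0.00602903
478,0.00629981
479,0.00657903
480,0.00686673
481,0.00716295
482,0.00746771
483,0.00778104
484,0.00810291
485,0.00843331
486,0.00877222
487,0.00911958
488,0.00947532
489,0.00983936
490,0.0102116
491,0.0105919
492,0.0109802
493,0.0113763
494,0.01178
495,0.0121911
496,0.0126094
497,0.0130347
498,0.0134668
499,0.0139054
500,0.0143501
501,0.0148007
502,0.0152569
503,0.0157184
504,0.0161848
505,0.0166557
506,0.0171308
507,0.0176097
508,0.018092
509,0.0185773
510,0.0190652
511,0.0195553
512,0.0200473
513,0.0205408
514,0.0210354
515,0.0215307
516,0.0220265
517,0.0225225
518,0.0230185
519,0.0235142
520,0.0240096
521,0.0245046
522,0.0249992
523,0.0254937
524,0.0259882
525,0.0264833
526,0.0269793
527,0.0274771
528,0.0279775
529,0.0284817
530,0.028991
531,0.0295071
532,0.0300319
533,0.0305676
534,0.0311168
535,0.0316825
536,0.032268
537,0.0328772
538,0.0335142
539,0.0341839
540,0.0348915
541,0.0356429
542,0.0364444
543,0.037303
544,0.0382263
545,0.0392224
546,0.0403003
547,0.0414692
548,0.0427393
549,0.0441211
550,0.0456257
551,0.0472649
552,0.0490508
553,0.0509959
554,0.0531131
555,0.0554155
556,0.0579164
557,0.060629
558,0.0635665
559,0.0667419
560,0.0701678
561,0.073856
562,0.077818
563,0.0820639
564,0.086603
565,0.0914433
566,0.0965911
567,0.102051
568,0.107826
569,0.113917
570,0.120321
571,0.127036
572,0.134053
573,0.141365
574,0.148957
575,0.156815
576,0.16492
577,0.173252
578,0.181784
579,0.19049
580,0.199339
581,0.208298
582,0.217331
583,0.226399
584,0.235462
585,0.244478
586,0.253404
587,0.262194
588,0.270804
589,0.279188
590,0.287301
591,0.295101
592,0.302546
593,0.309595
594,0.316214
595,0.322369
596,0.328033
597,0.333183
598,0.337803
599,0.341885
600,0.345424
601,0.348429
602,0.350915
603,0.352906
604,0.354438
605,0.355558
606,0.356321
607,0.356797
608,0.357065
609,0.357217
610,0.357356
611,0.357594
612,0.358055
613,0.358871
614,0.360181
615,0.362132
616,0.364873
617,0.368557
618,0.373336
619,0.379357
620,0.386763
621,0.395686
622,0.406245
623,0.418542
624,0.43266
625,0.448656
626,0.466563
627,0.486379
628,0.508074
629,0.531579
630,0.55679
631,0.583564
632,0.611721
633,0.64104
634,0.671269
635,0.702117
636,0.733267
637,0.764374
638,0.795072
639,0.82498
640,0.853708
641,0.880867
642,0.906071
643,0.928947
644,0.949146
645,0.966343
646,0.980251
647,0.990623
648,0.997256
649,1
650,0.998759
651,0.99349
652,0.98421
653,0.970991
654,0.953957
655,0.933288
656,0.909207
657,0.881982
658,0.851918
659,0.819348
660,0.784629
661,0.748135
662,0.710248
663,0.67135
664,0.631821
665,0.592025
666,0.552313
667,0.513011
668,0.474419
669,0.436806
670,0.400411
671,0.365436
672,0.33205
673,0.300389
674,0.27055
675,0.242604
676,0.216587
677,0.19251
678,0.170355
679,0.150088
680,0.131649
681,0.114968
682,0.0999597
683,0.0865286
684,0.0745734
685,0.0639882
686,0.054665
687,0.0464961
688,0.0393752
689,0.0331997
690,0.0278711
691,0.0232964
692,0.0193886
693,0.016067
694,0.0132575
695,0.0108929
696,0.00891239
697,0.00726155
698,0.00589211
699,0.0047615
700,0.00383249
701,0.00307269
702,0.00245415
703,0.00195293
704,0.0015486
705,0.00122389
706,0.000964249
707,0.000757536
708,0.000593644
709,0.000464225
710,0.000362425
711,0.000282643
712,0.000220332
713,0.000171819
714,0.000134154
715,0.000104981
716,8.24271e-05
717,6.50121e-05
718,5.15718e-05
719,4.11951e-05
720,3.31727e-05
721,2.69545e-05
722,2.21164e-05
723,1.83325e-05
724,1.53532e-05
725,1.29886e-05
726,1.10942e-05
727,9.56053e-06
728,8.30486e-06
729,7.26475e-06
730,6.39309e-06
731,5.6543e-06
732,5.02147e-06
733,4.47419e-06
734,3.99686e-06
735,3.57751e-06
736,3.20685e-06
737,2.87758e-06
738,2.58393e-06
739,2.32122e-06
740,2.08563e-06
741,1.874e-06
742,1.68365e-06
743,1.5123e-06
744,1.35798e-06
745,1.21896e-06
746,1.09371e-06
747,9.80882e-07
748,8.79271e-07
749,7.87788e-07
750,7.05456e-07
751,6.31392e-07
752,5.64797e-07
753,5.04949e-07
754,4.51193e-07
755,4.02935e-07
756,3.59638e-07
757,3.20812e-07
758,2.86017e-07
759,2.54852e-07
760,2.26954e-07
761,2.01996e-07
762,1.79681e-07
763,1.5974e-07
764,1.41933e-07
765,1.26038e-07
766,1.11861e-07
767,9.92217e-08
768,8.79608e-08
769,7.79338e-08
770,6.90107e-08
771,6.10746e-08
772,5.40205e-08
773,4.7754e-08
774,4.21906e-08
775,3.72542e-08
776,3.28767e-08
777,2.89971e-08
778,2.55609e-08
779,2.25191e-08
780,1.9828e-08
781,1.74486e-08
782,1.53461e-08
783,1.34892e-08
784,1.18503e-08
785,1.04047e-08
786,9.13018e-09
787,8.00726e-09
788,7.01848e-09
789,6.14831e-09
790,5.38297e-09
791,4.71023e-09
792,4.11923e-09
793,3.60034e-09
794,3.14504e-09
795,2.74575e-09
796,2.3958e-09
797,2.08926e-09
798,1.82092e-09
799,1.58614e-09
800,1.38085e-09
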