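# synthetic parametric stand-in spectrum; see stormsim.spectral
wavelength_nm,value
400,7.87234e-19
401,1.01766e-18
402,1.31446e-18
403,1.69643e-18
404,2.18761e-18
405,2.81871e-18
406,3.62891e-18
407,4.66818e-18
408,6.00019e-18
409,7.70596e-18
410,9.8886e-18
411,1.26791e-17
412,1.62438e-17
413,2.07937e-17
414,2.65962e-17
415,3.39903e-17
416,4.34046e-17
417,5.53812e-17
418,7.06047e-17
419,8.99395e-17
420,1.14476e-16
421,1.45586e-16
422,1.85001e-16
423,2.34895e-16
424,2.98001e-16
425,3.77753e-16
426,4.78457e-16
427,6.05513e-16
428,7.65684e-16
429,9.67434e-16
430,1.22135e-15
431,1.54064e-15
432,1.94182e-15
433,2.44548e-15
434,3.07725e-15
435,3.86907e-15
436,4.86068e-15
437,6.10144e-15
438,7.65268e-15
439,9.59047e-15
440,1.20091e-14
441,1.50255e-14
442,1.87842e-14
443,2.34639e-14
444,2.92856e-14
445,3.65219e-14
446,4.55091e-14
447,5.66616e-14
448,7.04895e-14
449,8.76205e-14
450,1.08826e-13
451,1.35053e-13
452,1.67464e-13
453,2.07484e-13
454,2.56858e-13
455,3.17722e-13
456,3.92688e-13
457,4.84945e-13
458,5.98388e-13
459,7.37766e-13
460,9.08867e-13
461,1.11873e-12
462,1.37594e-12
463,1.6909e-12
464,2.07625e-12
465,2.54735e-12
466,3.1228e-12
467,3.82511e-12
468,4.68154e-12
469,5.72505e-12
470,6.99545e-12
471,8.54077e-12
472,1.0419e-11
473,1.26998e-11
474,1.54673e-11
475,1.88225e-11
476,2.28869e-11
477,2.78062e-11
478,3.37553e-11
479,4.09437e-11
480,4.96224e-11
481,6.00917e-11
482,7.27104e-11
483,8.79071e-11
484,1.06193e-10
485,1.28178e-10
486,1.54589e-10
487,1.86289e-10
488,2.24307e-10
489,2.69863e-10
490,3.24406e-10
491,3.89654e-10
492,4.67645e-10
493,5.60787e-10
494,6.71932e-10
495,8.04449e-10
496,9.62314e-10
497,1.15022e-09
498,1.3737e-09
499,1.63925e-09
500,1.95454e-09
501,2.32858e-09
502,2.77193e-09
503,3.29701e-09
504,3.91834e-09
505,4.65296e-09
506,5.52081e-09
507,6.54518e-09
508,7.75328e-09
509,9.17689e-09
510,1.0853e-08
511,1.28248e-08
512,1.51425e-08
513,1.78644e-08
514,2.10584e-08
515,2.48032e-08
516,2.91901e-08
517,3.43249e-08
518,4.033e-08
519,4.7347e-08
520,5.55396e-08
521,6.50966e-08
522,7.62358e-08
523,8.92083e-08
524,1.04303e-07
525,1.21852e-07
526,1.42238e-07
527,1.65899e-07
528,1.93339e-07
529,2.25132e-07
530,2.6194e-07
531,3.04518e-07
532,3.53727e-07
533,4.10553e-07
534,4.76119e-07
535,5.51706e-07
536,6.3877e-07
537,7.38972e-07
538,8.54193e-07
539,9.86575e-07
540,1.13854e-06
541,1.31285e-06
542,1.5126e-06
543,1.74133e-06
544,2.003e-06
545,2.30212e-06
546,2.64375e-06
547,3.0336e-06
548,3.47809e-06
549,3.98446e-06
550,4.56083e-06
551,5.21631e-06
552,5.96113e-06
553,6.80674e-06
554,7.76596e-06
555,8.85313e-06
556,1.00843e-05
557,1.14772e-05
558,1.30519e-05
559,1.48306e-05
560,1.68379e-05
561,1.91013e-05
562,2.16513e-05
563,2.45218e-05
564,2.77501e-05
565,3.13779e-05
566,3.54511e-05
567,4.00204e-05
568,4.5142e-05
569,5.08777e-05
570,5.72957e-05
571,6.44711e-05
572,7.24866e-05
573,8.14331e-05
574,9.14105e-05
575,0.000102529
576,0.000114908
577,0.00012868
578,0.000143991
579,0.000160999
580,0.000179879
581,0.000200823
582,0.00022404
583,0.000249764
584,0.000278247
585,0.000309773
586,0.00034465
587,0.000383224
588,0.000425877
589,0.000473037
590,0.000525183
591,0.000582852
592,0.000646654
593,0.000717281
594,0.000795522
595,0.000882285
596,0.000978617
597,0.00108573
598,0.00120503
599,0.00133818
600,0.0014871
601,0.00165408
602,0.00184178
603,0.00205336
604,0.00229256
605,0.00256376
606,0.00287217
607,0.00322388
608,0.00362609
609,0.00408723
610,0.00461719
611,0.00522747
612,0.00593149
613,0.00674477
614,0.00768524
615,0.00877346
616,0.010033
617,0.0114906
618,0.0131767
619,0.0151253
620,0.0173747
621,0.0199674
622,0.0229505
623,0.0263755
624,0.0302989
625,0.0347816
626,0.0398892
627,0.0456916
628,0.0522623
629,0.0596787
630,0.0680203
631,0.0773689
632,0.0878068
633,0.0994159
634,0.112276
635,0.126465
636,0.142052
637,0.159103
638,0.177673
639,0.197806
640,0.219533
641,0.242869
642,0.267814
643,0.294345
644,0.322422
645,0.35198
646,0.382931
647,0.415163
648,0.448539
649,0.482898
650,0.518053
651,0.553797
652,0.589899
653,0.62611
654,0.662164
655,0.697785
656,0.732683
657,0.766566
658,0.79914
659,0.830114
660,0.859209
661,0.886154
662,0.910701
663,0.932621
664,0.951714
665,0.967807
666,0.980765
667,0.990486
668,0.996905
669,1
670,0.999785
671,0.996313
672,0.989678
673,0.980007
674,0.967462
675,0.952234
676,0.934543
677,0.914628
678,0.89275
679,0.86918
680,0.844199
681,0.818092
682,0.791143
683,0.763631
684,0.735824
685,0.70798
686,0.680338
687,0.65312
688,0.626526
689,0.600733
690,0.575894
691,0.552139
692,0.529571
693,0.508271
694,0.488295
695,0.469678
696,0.452433
697,0.436557
698,0.422026
699,0.408803
700,0.396839
701,0.386074
702,0.376436
703,0.367851
704,0.360238
705,0.353514
706,0.347591
707,0.342387
708,0.337816
709,0.333798
710,0.330253
711,0.327107
712,0.32429
713,0.321737
714,0.319388
715,0.317187
716,0.315086
717,0.313038
718,0.311006
719,0.308954
720,0.306851
721,0.304674
722,0.302398
723,0.300008
724,0.297487
725,0.294826
726,0.292015
727,0.289048
728,0.285921
729,0.282634
730,0.279185
731,0.275577
732,0.271812
733,0.267896
734,0.263833
735,0.259629
736,0.255291
737,0.250826
738,0.246244
739,0.241552
740,0.236758
741,0.231873
742,0.226905
743,0.221863
744,0.216758
745,0.211597
746,0.206392
747,0.201151
748,0.195884
749,0.190599
750,0.185305
751,0.180012
752,0.174727
753,0.169459
754,0.164216
755,0.159005
756,0.153834
757,0.14871
758,0.143639
759,0.138627
760,0.133682
761,0.128808
762,0.12401
763,0.119293
764,0.114663
765,0.110122
766,0.105674
767,0.101324
768,0.097073
769,0.0929247
770,0.0888811
771,0.0849441
772,0.0811153
773,0.0773958
774,0.0737866
775,0.0702883
776,0.0669013
777,0.0636255
778,0.0604607
779,0.0574065
780,0.054462
781,0.0516265
782,0.0488986
783,0.0462771
784,0.0437604
785,0.0413467
786,0.0390344
787,0.0368213
788,0.0347053
789,0.0326842
790,0.0307557
791,0.0289174
792,0.0271667
793,0.0255013
794,0.0239184
795,0.0224154
796,0.0209898
797,0.0196387
798,0.0183597
799,0.0171499
800,0.0160068
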