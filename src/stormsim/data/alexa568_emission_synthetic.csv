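# synthetic parametric stand-in spectrum; see stormsim.spectral
wavelength_nm,value
400,2.54594e-12
401,3.12106e-12
402,3.82297e-12
403,4.67893e-12
404,5.72186e-12
405,6.99155e-12
406,8.53601e-12
407,1.04132e-11
408,1.26927e-11
409,1.54587e-11
410,1.88121e-11
411,2.28742e-11
412,2.77907e-11
413,3.37365e-11
414,4.09209e-11
415,4.95948e-11
416,6.00582e-11
417,7.26699e-11
418,8.78581e-11
419,1.06134e-10
420,1.28107e-10
421,1.54503e-10
422,1.86185e-10
423,2.24182e-10
424,2.69712e-10
425,3.24225e-10
426,3.89437e-10
427,4.67384e-10
428,5.60475e-10
429,6.71558e-10
430,8.04001e-10
431,9.61778e-10
432,1.14958e-09
433,1.37293e-09
434,1.63834e-09
435,1.95346e-09
436,2.32728e-09
437,2.77039e-09
438,3.29517e-09
439,3.91615e-09
440,4.65037e-09
441,5.51773e-09
442,6.54153e-09
443,7.74896e-09
444,9.17177e-09
445,1.0847e-08
446,1.28177e-08
447,1.5134e-08
448,1.78545e-08
449,2.10467e-08
450,2.47894e-08
451,2.91739e-08
452,3.43058e-08
453,4.03076e-08
454,4.73207e-08
455,5.55086e-08
456,6.50603e-08
457,7.61933e-08
458,8.91586e-08
459,1.04245e-07
460,1.21785e-07
461,1.42159e-07
462,1.65807e-07
463,1.93231e-07
464,2.25007e-07
465,2.61794e-07
466,3.04348e-07
467,3.5353e-07
468,4.10324e-07
469,4.75854e-07
470,5.51398e-07
471,6.38415e-07
472,7.3856e-07
473,8.53717e-07
474,9.86025e-07
475,1.13791e-06
476,1.31212e-06
477,1.51176e-06
478,1.74036e-06
479,2.00189e-06
480,2.30084e-06
481,2.64228e-06
482,3.03192e-06
483,3.47617e-06
484,3.98226e-06
485,4.55832e-06
486,5.21345e-06
487,5.95787e-06
488,6.80304e-06
489,7.76177e-06
490,8.8484e-06
491,1.00789e-05
492,1.14713e-05
493,1.30453e-05
494,1.48233e-05
495,1.68299e-05
496,1.90927e-05
497,2.16422e-05
498,2.45122e-05
499,2.77406e-05
500,3.13689e-05
501,3.54433e-05
502,4.0015e-05
503,4.51407e-05
504,5.08828e-05
505,5.73106e-05
506,6.45004e-05
507,7.25367e-05
508,8.15129e-05
509,9.15319e-05
510,0.000102708
511,0.000115167
512,0.000129049
513,0.000144509
514,0.000161718
515,0.000180868
516,0.000202172
517,0.000225869
518,0.000252227
519,0.000281545
520,0.000314163
521,0.000350467
522,0.000390892
523,0.000435938
524,0.000486179
525,0.000542271
526,0.000604977
527,0.000675177
528,0.000753899
529,0.000842336
530,0.000941887
531,0.00105419
532,0.00118116
533,0.00132504
534,0.00148848
535,0.00167459
536,0.00188698
537,0.00212992
538,0.0024084
539,0.00272823
540,0.00309618
541,0.00352014
542,0.00400922
543,0.00457398
544,0.00522654
545,0.00598084
546,0.00685279
547,0.00786049
548,0.00902447
549,0.0103679
550,0.0119167
551,0.0136999
552,0.0157499
553,0.0181023
554,0.0207963
555,0.0238749
556,0.0273844
557,0.0313753
558,0.0359014
559,0.04102
560,0.0467915
561,0.0532795
562,0.0605496
563,0.0686695
564,0.0777078
565,0.0877336
566,0.0988152
567,0.111019
568,0.12441
569,0.139046
570,0.154982
571,0.172264
572,0.19093
573,0.21101
574,0.232518
575,0.255459
576,0.27982
577,0.305575
578,0.332678
579,0.361066
580,0.39066
581,0.421356
582,0.453035
583,0.485559
584,0.518767
585,0.552484
586,0.586517
587,0.62066
588,0.65469
589,0.688378
590,0.721484
591,0.753766
592,0.784979
593,0.814879
594,0.843228
595,0.869798
596,0.894372
597,0.916749
598,0.936747
599,0.954206
600,0.96899
601,0.980991
602,0.990128
603,0.99635
604,0.999637
605,1
606,0.99748
607,0.992149
608,0.984106
609,0.973478
610,0.960415
611,0.94509
612,0.927695
613,0.908437
614,0.887536
615,0.865221
616,0.841725
617,0.817285
618,0.792135
619,0.766504
620,0.740614
621,0.714678
622,0.688894
623,0.663446
624,0.638501
625,0.614211
626,0.590707
627,0.5681
628,0.546484
629,0.525933
630,0.506502
631,0.48823
632,0.471136
633,0.455227
634,0.440492
635,0.426909
636,0.414446
637,0.403059
638,0.392696
639,0.383299
640,0.374806
641,0.367149
642,0.360259
643,0.354064
644,0.348495
645,0.343481
646,0.338954
647,0.334847
648,0.331099
649,0.327648
650,0.324439
651,0.32142
652,0.318544
653,0.315766
654,0.313047
655,0.310353
656,0.307652
657,0.304917
658,0.302124
659,0.299254
660,0.29629
661,0.293218
662,0.290028
663,0.286712
664,0.283263
665,0.279679
666,0.275957
667,0.272098
668,0.268103
669,0.263975
670,0.259718
671,0.255337
672,0.250838
673,0.246227
674,0.241513
675,0.236702
676,0.231804
677,0.226825
678,0.221776
679,0.216666
680,0.211502
681,0.206295
682,0.201052
683,0.195785
684,0.1905
685,0.185208
686,0.179916
687,0.174633
688,0.169367
689,0.164126
690,0.158918
691,0.153749
692,0.148627
693,0.143559
694,0.138551
695,0.133608
696,0.128736
697,0.123941
698,0.119227
699,0.114599
700,0.11006
701,0.105615
702,0.101267
703,0.0970189
704,0.092873
705,0.0888316
706,0.0848968
707,0.0810701
708,0.0773527
709,0.0737455
710,0.0702492
711,0.066864
712,0.06359
713,0.060427
714,0.0573745
715,0.0544317
716,0.0515977
717,0.0488714
718,0.0462513
719,0.043736
720,0.0413237
721,0.0390126
722,0.0368007
723,0.0346859
724,0.032666
725,0.0307386
726,0.0289013
727,0.0271516
728,0.0254871
729,0.023905
730,0.0224029
731,0.0209781
732,0.0196278
733,0.0183495
734,0.0171404
735,0.0159979
736,0.0149194
737,0.0139022
738,0.0129438
739,0.0120417
740,0.0111933
741,0.0103962
742,0.00964792
743,0.00894623
744,0.0082888
745,0.00767342
746,0.00709793
747,0.00656025
748,0.00605834
749,0.00559027
750,0.00515416
751,0.00474819
752,0.00437062
753,0.0040198
754,0.00369412
755,0.00339206
756,0.00311215
757,0.00285301
758,0.00261332
759,0.00239181
760,0.00218728
761,0.00199862
762,0.00182474
763,0.00166462
764,0.00151732
765,0.00138192
766,0.00125758
767,0.0011435
768,0.00103891
769,0.000943118
770,0.000855461
771,0.000775318
772,0.00070211
773,0.000635295
774,0.00057437
775,0.000518863
776,0.000468339
777,0.000422389
778,0.000380636
779,0.000342731
780,0.000308349
781,0.00027719
782,0.000248976
783,0.000223451
784,0.000200379
785,0.000179543
786,0.000160743
787,0.000143793
788,0.000128526
789,0.000114786
790,0.000102431
791,9.13317e-05
792,8.13685e-05
793,7.24329e-05
794,6.44261e-05
795,5.72575e-05
796,5.08451e-05
797,4.5114e-05
798,3.99962e-05
799,3.543e-05
800,3.13595e-05
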