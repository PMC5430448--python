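# synthetic parametric stand-in spectrum; see stormsim.spectral
wavelength_nm,value
400,0.00196843
401,0.00209473
402,0.00222774
403,0.00236772
404,0.00251491
405,0.00266959
406,0.00283202
407,0.00300244
408,0.00318114
409,0.00336837
410,0.00356438
411,0.00376945
412,0.00398382
413,0.00420776
414,0.00444151
415,0.00468532
416,0.00493942
417,0.00520405
418,0.00547944
419,0.0057658
420,0.00606334
421,0.00637225
422,0.00669273
423,0.00702494
424,0.00736904
425,0.00772519
426,0.0080935
427,0.0084741
428,0.00886707
429,0.00927251
430,0.00969047
431,0.010121
432,0.0105641
433,0.0110198
434,0.011488
435,0.0119688
436,0.0124621
437,0.0129678
438,0.0134857
439,0.0140158
440,0.014558
441,0.0151121
442,0.0156779
443,0.0162553
444,0.016844
445,0.0174439
446,0.0180549
447,0.0186766
448,0.019309
449,0.0199519
450,0.0206052
451,0.0212687
452,0.0219424
453,0.0226263
454,0.0233205
455,0.024025
456,0.0247402
457,0.0254663
458,0.0262038
459,0.0269533
460,0.0277156
461,0.0284916
462,0.0292824
463,0.0300895
464,0.0309145
465,0.0317593
466,0.0326262
467,0.0335176
468,0.0344367
469,0.0353867
470,0.0363713
471,0.037395
472,0.0384622
473,0.0395784
474,0.0407492
475,0.041981
476,0.0432807
477,0.0446558
478,0.0461145
479,0.0476655
480,0.0493181
481,0.0510824
482,0.0529689
483,0.0549886
484,0.0571534
485,0.0594753
486,0.061967
487,0.0646414
488,0.0675119
489,0.070592
490,0.0738952
491,0.0774352
492,0.0812255
493,0.0852793
494,0.0896094
495,0.0942281
496,0.0991467
497,0.104376
498,0.109925
499,0.115802
500,0.122015
501,0.128566
502,0.135461
503,0.142699
504,0.15028
505,0.1582
506,0.166451
507,0.175027
508,0.183913
509,0.193096
510,0.202558
511,0.212277
512,0.22223
513,0.23239
514,0.242726
515,0.253206
516,0.263794
517,0.274452
518,0.28514
519,0.295816
520,0.306436
521,0.316955
522,0.32733
523,0.337513
524,0.347461
525,0.35713
526,0.366479
527,0.37547
528,0.384067
529,0.39224
530,0.399965
531,0.407223
532,0.414003
533,0.420303
534,0.426128
535,0.431497
536,0.436437
537,0.440989
538,0.445205
539,0.44915
540,0.452903
541,0.456555
542,0.460212
543,0.463988
544,0.468013
545,0.472422
546,0.47736
547,0.482977
548,0.489425
549,0.496854
550,0.505413
551,0.515237
552,0.526452
553,0.539165
554,0.553461
555,0.569398
556,0.587003
557,0.606267
558,0.627145
559,0.649548
560,0.673345
561,0.69836
562,0.724374
563,0.751126
564,0.778311
565,0.805594
566,0.832605
567,0.858952
568,0.884223
569,0.908003
570,0.929871
571,0.949422
572,0.966266
573,0.980043
574,0.990433
575,0.997159
576,1
577,0.998792
578,0.993434
579,0.983895
580,0.970206
581,0.95247
582,0.930849
583,0.90557
584,0.876912
585,0.845201
586,0.810805
587,0.774121
588,0.73557
589,0.695583
590,0.654597
591,0.613041
592,0.571331
593,0.52986
594,0.488996
595,0.449072
596,0.410381
597,0.37318
598,0.33768
599,0.304053
600,0.272425
601,0.242885
602,0.215482
603,0.190231
604,0.167114
605,0.146087
606,0.127081
607,0.110009
608,0.0947683
609,0.0812445
610,0.0693159
611,0.0588565
612,0.0497388
613,0.0418366
614,0.0350268
615,0.0291915
616,0.0242191
617,0.0200053
618,0.0164539
619,0.0134766
620,0.0109939
621,0.00893426
622,0.00723437
623,0.00583835
624,0.00469744
625,0.00376939
626,0.00301792
627,0.00241206
628,0.0019256
629,0.00153649
630,0.00122635
631,0.000979909
632,0.000784604
633,0.000630148
634,0.000508177
635,0.000411927
636,0.000335964
637,0.000275947
638,0.000228424
639,0.00019067
640,0.000160538
641,0.00013635
642,0.000116796
643,0.00010086
644,8.77543e-05
645,7.68723e-05
646,6.77456e-05
647,6.00139e-05
648,5.33997e-05
649,4.76892e-05
650,4.27173e-05
651,3.83555e-05
652,3.45038e-05
653,3.10833e-05
654,2.80314e-05
655,2.5298e-05
656,2.28422e-05
657,2.06304e-05
658,1.86348e-05
659,1.68316e-05
660,1.52006e-05
661,1.37245e-05
662,1.23878e-05
663,1.11772e-05
664,1.00808e-05
665,9.08779e-06
666,8.18866e-06
667,7.37476e-06
668,6.63826e-06
669,5.97206e-06
670,5.36974e-06
671,4.82543e-06
672,4.3338e-06
673,3.88998e-06
674,3.48956e-06
675,3.12849e-06
676,2.8031e-06
677,2.51003e-06
678,2.24624e-06
679,2.00895e-06
680,1.79563e-06
681,1.60397e-06
682,1.43189e-06
683,1.27748e-06
684,1.13902e-06
685,1.01494e-06
686,9.03811e-07
687,8.04352e-07
688,7.15393e-07
689,6.35877e-07
690,5.64847e-07
691,5.0144e-07
692,4.44872e-07
693,3.9444e-07
694,3.49507e-07
695,3.095e-07
696,2.73901e-07
697,2.42245e-07
698,2.14114e-07
699,1.89132e-07
700,1.6696e-07
701,1.47296e-07
702,1.29866e-07
703,1.14427e-07
704,1.00761e-07
705,8.86715e-08
706,7.79837e-08
707,6.85414e-08
708,6.02047e-08
709,5.28489e-08
710,4.63629e-08
711,4.06475e-08
712,3.56144e-08
713,3.1185e-08
714,2.72894e-08
715,2.38656e-08
716,2.08582e-08
717,1.82185e-08
718,1.59029e-08
719,1.38729e-08
720,1.20945e-08
721,1.05375e-08
722,9.17515e-09
723,7.98397e-09
724,6.9431e-09
725,6.03415e-09
726,5.24093e-09
727,4.54913e-09
728,3.94618e-09
729,3.42101e-09
730,2.96388e-09
731,2.56622e-09
732,2.22054e-09
733,1.92021e-09
734,1.65947e-09
735,1.43324e-09
736,1.23707e-09
737,1.06709e-09
738,9.19889e-10
739,7.92499e-10
740,6.82323e-10
741,5.87098e-10
742,5.04846e-10
743,4.33847e-10
744,3.72599e-10
745,3.19798e-10
746,2.74309e-10
747,2.35142e-10
748,2.01442e-10
749,1.72464e-10
750,1.47563e-10
751,1.26178e-10
752,1.07824e-10
753,9.20831e-11
754,7.85907e-11
755,6.70334e-11
756,5.71399e-11
757,4.86762e-11
758,4.14403e-11
759,3.52579e-11
760,2.99792e-11
761,2.54748e-11
762,2.16337e-11
763,1.83603e-11
764,1.55725e-11
765,1.31997e-11
766,1.11814e-11
767,9.46585e-12
768,8.0085e-12
769,6.77129e-12
770,5.72163e-12
771,4.83166e-12
772,4.07758e-12
773,3.43904e-12
774,2.89867e-12
775,2.44169e-12
776,2.05547e-12
777,1.72926e-12
778,1.45391e-12
779,1.22164e-12
780,1.02583e-12
781,8.60872e-13
782,7.21988e-13
783,6.05132e-13
784,5.06872e-13
785,4.24302e-13
786,3.54961e-13
787,2.96767e-13
788,2.47958e-13
789,2.07047e-13
790,1.72778e-13
791,1.44091e-13
792,1.20092e-13
793,1.00028e-13
794,8.32634e-14
795,6.92655e-14
796,5.75848e-14
797,4.7844e-14
798,3.97261e-14
799,3.2965e-14
800,2.73375e-14
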