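# CIE 1951 scotopic luminous efficiency function V'(lambda);
# 5 nm tabulation, 380-780 nm. Peak value 1.000 lies at 507 nm in the
# fine-grained tabulation; on this 5 nm grid the tabulated maximum is
# 0.998 at 505 nm. Source standard: CIE 018 / ISO 23539 scotopic table.
# Transcribed 2026-09; values reproduce the published abridged table.
wavelength_nm,vprime
380,0.000589
385,0.001108
390,0.002209
395,0.004530
400,0.009290
405,0.018520
410,0.034840
415,0.060400
420,0.096600
425,0.143600
430,0.199800
435,0.262500
440,0.328100
445,0.393100
450,0.455000
455,0.513000
460,0.567000
465,0.620000
470,0.676000
475,0.734000
480,0.793000
485,0.851000
490,0.904000
495,0.949000
500,0.982000
505,0.998000
510,0.997000
515,0.975000
520,0.935000
525,0.880000
530,0.811000
535,0.733000
540,0.650000
545,0.564000
550,0.481000
555,0.402000
560,0.328800
565,0.263900
570,0.207600
575,0.160200
580,0.121200
585,0.089900
590,0.065500
595,0.046900
600,0.033150
605,0.023120
610,0.015930
615,0.010880
620,0.007370
625,0.004970
630,0.003335
635,0.002235
640,0.001497
645,0.001005
650,0.000677
655,0.000459
660,0.000313
665,0.000215
670,0.000148
675,0.000103
680,0.000072
685,0.000050
690,0.000035
695,0.000025
700,0.000018
705,0.000013
710,0.000009
715,0.000007
720,0.000005
725,0.000003
730,0.000003
735,0.000002
740,0.000001
745,0.000001
750,0.000001
755,0.000001
760,0.000000
765,0.000000
770,0.000000
775,0.000000
780,0.000000
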