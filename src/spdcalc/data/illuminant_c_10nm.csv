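# CIE Illuminant C relative spectral power distribution, normalised to
# 100 at 560 nm. 10 nm tabulation, 380-780 nm.
# Source standard: CIE 015 (colorimetry), Illuminant C table.
# Transcribed 2026-09; values reproduce the published abridged table.
wavelength_nm,value
380,33.00
390,47.40
400,63.30
410,80.60
420,98.10
430,112.40
440,121.50
450,124.00
460,123.10
470,123.80
480,123.90
490,120.70
500,112.10
510,102.30
520,96.90
530,98.00
540,102.10
550,105.20
560,105.30
570,102.30
580,97.80
590,93.20
600,89.70
610,88.40
620,88.10
630,88.00
640,87.80
650,88.20
660,87.90
670,86.30
680,84.00
690,80.20
700,76.30
710,72.40
720,68.30
730,64.40
740,61.50
750,59.20
760,58.10
770,58.20
780,59.10
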