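wavelength_nm,mu_a_cm1
670,0.006
680,0.00572222
690,0.00555556
700,0.0055
710,0.00557407
720,0.00575926
730,0.006
740,0.0065
750,0.00716667
760,0.0075
770,0.00742187
780,0.00725
790,0.00707813
800,0.007
810,0.00707568
820,0.00728704
830,0.00761057
840,0.00802273
850,0.0085
860,0.00915882
870,0.0102608
880,0.012
890,0.0171735
900,0.027
910,0.0464019
920,0.075
930,0.112
940,0.08
950,0.045
960,0.0376136
970,0.035
980,0.0357537
990,0.0376184
1000,0.04
1010,0.0444985
1020,0.0512209
1030,0.0573328
1040,0.06
1050,0.0560352
1060,0.0495164
1070,0.0466884
1080,0.0447994
1090,0.0434899
1100,0.043
1110,0.0448209
1120,0.0499428
1130,0.0578541
1140,0.0680437
1150,0.08
1160,0.10102
1170,0.136658
1180,0.183785
1190,0.239275
1200,0.3
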