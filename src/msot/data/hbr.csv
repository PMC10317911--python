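wavelength_nm,mu_a_cm1
670,15.9
680,12.9
690,11.0623
700,9.61
710,8.01465
720,6.5451
730,5.9
740,6.51913
750,7.53
760,8.29
770,7.29386
780,5.79
790,4.72078
800,4.08
810,3.93901
820,3.83209
830,3.75766
840,3.71415
850,3.7
860,3.72859
870,3.80098
880,3.89707
890,3.99677
900,4.08
910,4.14977
920,4.21977
930,4.28588
940,4.344
950,4.39
960,4.42925
970,4.46706
980,4.49924
990,4.52161
1000,4.53
1010,4.51694
1020,4.48145
1030,4.42911
1040,4.36548
1050,4.29612
1060,4.22661
1070,4.1565
1080,4.07054
1090,3.98023
1100,3.9
1110,3.83335
1120,3.77252
1130,3.71501
1140,3.65834
1150,3.6
1160,3.54
1170,3.48
1180,3.42
1190,3.36
1200,3.3
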