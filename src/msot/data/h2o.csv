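wavelength_nm,mu_a_cm1
670,0.0042
680,0.00443243
690,0.00506486
700,0.006
710,0.00910515
720,0.0143965
730,0.019
740,0.0225414
750,0.0256596
760,0.027
770,0.0252
780,0.023
790,0.0223
800,0.022
810,0.0234536
820,0.0272007
830,0.032321
840,0.0378943
850,0.043
860,0.0471331
870,0.0509209
880,0.0551422
890,0.0605757
900,0.068
910,0.0798706
920,0.101288
930,0.137
940,0.27
950,0.359518
960,0.42
970,0.45
980,0.46
990,0.421194
1000,0.36
1010,0.316371
1020,0.275927
1030,0.24
1040,0.203418
1050,0.16816
1060,0.146294
1070,0.145658
1080,0.15489
1090,0.170376
1100,0.19
1110,0.228789
1120,0.295981
1130,0.380777
1140,0.472383
1150,0.56
1160,0.644175
1170,0.732497
1180,0.824732
1190,0.920644
1200,1.02
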