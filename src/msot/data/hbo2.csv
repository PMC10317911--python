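wavelength_nm,mu_a_cm1
670,1.71
680,1.59741
690,1.55593
700,1.55
710,1.63717
720,1.84434
730,2.09
740,2.39491
750,2.77466
760,3.14
770,3.46391
780,3.77787
790,4.0804
800,4.37
810,4.65565
820,4.93978
830,5.21109
840,5.45827
850,5.67
860,5.8517
870,6.01679
880,6.16604
890,6.3002
900,6.42
910,6.54276
920,6.65249
930,6.7
940,6.67732
950,6.61619
960,6.52697
970,6.42
980,6.21563
990,5.91952
1000,5.67
1010,5.5045
1020,5.36288
1030,5.23712
1040,5.11918
1050,5.00104
1060,4.87466
1070,4.73326
1080,4.58176
1090,4.43056
1100,4.29
1110,4.16162
1120,4.0394
1130,3.92237
1140,3.80956
1150,3.7
1160,3.59328
1170,3.48974
1180,3.38956
1190,3.29292
1200,3.2
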