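wavelength_nm,mu_a_cm1
670,18.7432
680,17.8013
690,16.9195
700,16.0932
710,15.3181
720,14.5904
730,13.9066
740,13.2635
750,12.6581
760,12.0879
770,11.5504
780,11.0432
790,10.5643
800,10.1118
810,9.68401
820,9.2792
830,8.89593
840,8.53279
850,8.18851
860,7.86192
870,7.5519
880,7.25744
890,6.97759
900,6.71149
910,6.45831
920,6.21729
930,5.98773
940,5.76897
950,5.56038
960,5.36141
970,5.17151
980,4.99018
990,4.81695
1000,4.65139
1010,4.49308
1020,4.34165
1030,4.19671
1040,4.05795
1050,3.92504
1060,3.79768
1070,3.67559
1080,3.55851
1090,3.44619
1100,3.33839
1110,3.23489
1120,3.13548
1130,3.03997
1140,2.94818
1150,2.85992
1160,2.77504
1170,2.69337
1180,2.61477
1190,2.5391
1200,2.46622
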