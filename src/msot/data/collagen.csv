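wavelength_nm,mu_a_cm1
670,0.028
680,0.0256296
690,0.0235926
700,0.022
710,0.0208074
720,0.019837
730,0.019
740,0.0182538
750,0.0175964
760,0.017
770,0.0163639
780,0.0157123
790,0.0152046
800,0.015
810,0.0151056
820,0.0153968
830,0.0158352
840,0.0163824
850,0.017
860,0.0179331
870,0.0193512
880,0.0211028
890,0.0230363
900,0.025
910,0.0271914
920,0.0296529
930,0.032
940,0.0339916
950,0.0358158
960,0.0377321
970,0.04
980,0.0428282
990,0.0461919
1000,0.05
1010,0.0556667
1020,0.062
1030,0.065
1040,0.0635396
1050,0.0605831
1060,0.0582679
1070,0.0586616
1080,0.062256
1090,0.0680529
1100,0.075
1110,0.0845057
1120,0.0983116
1130,0.115865
1140,0.136612
1150,0.16
1160,0.189376
1170,0.227498
1180,0.272932
1190,0.324244
1200,0.38
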