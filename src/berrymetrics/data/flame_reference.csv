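bunch_id,n_total,r_mean_total_mm,r_sd_total_mm,view_index,n_visible,r_mean_px
Bunch_01,47,10.1,0.35,1,30,25
Bunch_01,47,10.1,0.35,2,28,23
Bunch_01,47,10.1,0.35,3,26,21
Bunch_02,52,9.3,0.52,1,37,21
Bunch_02,52,9.3,0.52,2,32,21
Bunch_02,52,9.3,0.52,3,41,19
Bunch_03,36,9.3,0.44,1,21,24
Bunch_03,36,9.3,0.44,2,25,23
Bunch_03,36,9.3,0.44,3,24,19
Bunch_04,39,9.2,0.59,1,23,25
Bunch_04,39,9.2,0.59,2,23,22
Bunch_04,39,9.2,0.59,3,21,19
Bunch_05,55,9.5,0.57,1,31,24
Bunch_05,55,9.5,0.57,2,31,23
Bunch_05,55,9.5,0.57,3,27,22
Bunch_06,51,10.1,0.36,1,32,23
Bunch_06,51,10.1,0.36,2,35,22
Bunch_06,51,10.1,0.36,3,29,25
Bunch_07,63,9.8,0.42,1,33,22
Bunch_07,63,9.8,0.42,2,39,21
Bunch_07,63,9.8,0.42,3,34,22
Bunch_08,52,10.1,0.45,1,30,22
Bunch_08,52,10.1,0.45,2,34,21
Bunch_08,52,10.1,0.45,3,29,21
Bunch_09,76,9.5,0.40,1,41,20
Bunch_09,76,9.5,0.40,2,43,20
Bunch_09,76,9.5,0.40,3,48,19
Bunch_10,40,9.5,0.38,1,29,22
Bunch_10,40,9.5,0.38,2,24,21
Bunch_10,40,9.5,0.38,3,24,20
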