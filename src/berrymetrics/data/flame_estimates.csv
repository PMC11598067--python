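bunch_id,view_index,n_est_printed,diff_printed
Bunch_01,1,30,0
Bunch_01,2,28,0
Bunch_01,3,26,0
Bunch_02,1,32,-5
Bunch_02,2,35,3
Bunch_02,3,38,-3
Bunch_03,1,20,-1
Bunch_03,2,24,-1
Bunch_03,3,23,-1
Bunch_04,1,22,-1
Bunch_04,2,23,0
Bunch_04,3,20,-1
Bunch_05,1,28,-3
Bunch_05,2,28,-3
Bunch_05,3,21,-6
Bunch_06,1,33,1
Bunch_06,2,37,2
Bunch_06,3,36,-3
Bunch_07,1,31,-2
Bunch_07,2,36,-3
Bunch_07,3,31,-3
Bunch_08,1,28,-2
Bunch_08,2,30,1
Bunch_08,3,29,0
Bunch_09,1,38,-3
Bunch_09,2,42,-1
Bunch_09,3,45,-3
Bunch_10,1,24,-5
Bunch_10,2,23,-1
Bunch_10,3,24,0
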