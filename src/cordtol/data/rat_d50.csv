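study,site,follow_up_days,d50_gy,n_fractions
Karger,cervical,300,24.5,1
Karger,cervical,300,34.3,2
Karger,cervical,300,57,6
Karger,cervical,300,88.6,18
Ang,cervical,210,22.4,1
Ang,cervical,210,30.4,2
Ang,cervical,210,43.4,4
Ang,cervical,210,63,10
Van der Kogel (C),cervical,365,19,1
Van der Kogel (C),cervical,365,27,2
Van der Kogel (C),cervical,365,37.8,5
Van der Kogel (C),cervical,365,55,10
Van der Kogel (C),cervical,365,80,30
White,lumbar,365,24,1
White,lumbar,365,33,2
White,lumbar,365,46,4
White,lumbar,365,59,8
White,lumbar,365,68,15
White,lumbar,365,92,30
Masuda,thoracic,455,25.5,1
Masuda,thoracic,455,34.5,2
Masuda,thoracic,455,46.6,4
Van der Kogel (L),lumbar,365,19.5,1
Van der Kogel (L),lumbar,365,27,2
Van der Kogel (L),lumbar,365,32.1,3
Van der Kogel (L),lumbar,365,36.8,5
Van der Kogel (L),lumbar,365,47.7,10
Van der Kogel (L),lumbar,365,60.4,15
Van der Kogel (L),lumbar,365,67.1,20
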