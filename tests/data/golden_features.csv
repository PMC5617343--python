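post_id,NumPost,NumUser,AvgLen,NumName,NumNeg,NumPos,NumCAM,NumOverlap,Num?,Num!,TimeDif,Sig,NAgree,NDisagree
t0p000,9,3,17.22222222222222,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
t0p001,9,3,17.22222222222222,0.0,0.0,0.0,0.0,1.0,0.0,0.0,37246.0,0.0,0.0,0.0
t0p002,9,3,17.22222222222222,1.0,0.0,0.0,0.0,3.0,0.0,0.0,32972.0,0.0,0.0,0.0
t0p003,9,3,17.22222222222222,1.0,0.0,0.0,0.0,3.0,0.0,0.0,64098.0,0.0,0.0,0.0
t0p004,9,3,17.22222222222222,1.0,0.0,0.0,2.0,6.0,0.0,1.0,26019.0,0.0,1.0,0.0
t0p005,9,3,17.22222222222222,1.0,0.0,0.0,0.0,6.0,0.0,0.0,6480.0,0.0,0.0,1.0
t0p006,9,3,17.22222222222222,1.0,0.0,0.0,0.0,2.0,0.0,0.0,53020.0,0.0,1.0,0.0
t0p007,9,3,17.22222222222222,0.0,0.0,0.0,0.0,3.0,1.0,0.0,72324.0,0.0,0.0,0.0
t0p008,9,3,17.22222222222222,0.0,0.0,0.0,0.0,2.0,1.0,0.0,67124.0,0.0,0.0,0.0
t1p000,9,5,17.444444444444443,2.0,0.0,0.0,3.0,0.0,1.0,0.0,0.0,0.0,0.0,0.0
t1p001,9,5,17.444444444444443,0.0,0.0,0.0,1.0,9.0,0.0,0.0,69762.0,0.0,0.0,0.0
t1p002,9,5,17.444444444444443,0.0,0.0,0.0,0.0,2.0,1.0,0.0,21177.0,0.0,0.0,1.0
t1p003,9,5,17.444444444444443,0.0,0.0,0.0,0.0,3.0,0.0,0.0,62342.0,0.0,1.0,0.0
t1p004,9,5,17.444444444444443,0.0,0.0,0.0,0.0,2.0,0.0,0.0,11920.0,0.0,0.0,0.0
t1p005,9,5,17.444444444444443,0.0,0.0,0.0,0.0,2.0,0.0,0.0,86223.0,0.0,0.0,1.0
t1p006,9,5,17.444444444444443,0.0,0.0,0.0,0.0,2.0,1.0,0.0,62708.0,0.0,0.0,0.0
t1p007,9,5,17.444444444444443,0.0,0.0,0.0,0.0,2.0,0.0,0.0,53289.0,0.0,0.0,0.0
t1p008,9,5,17.444444444444443,0.0,0.0,0.0,0.0,6.0,0.0,0.0,16256.0,0.0,0.0,0.0
t2p000,9,4,18.11111111111111,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
t2p001,9,4,18.11111111111111,0.0,0.0,0.0,0.0,0.0,0.0,1.0,51841.0,0.0,0.0,0.0
t2p002,9,4,18.11111111111111,0.0,0.0,0.0,0.0,3.0,0.0,0.0,54408.0,0.0,0.0,0.0
t2p003,9,4,18.11111111111111,0.0,0.0,0.0,0.0,2.0,0.0,0.0,41122.0,0.0,0.0,0.0
t2p004,9,4,18.11111111111111,0.0,0.0,0.0,0.0,2.0,0.0,0.0,66537.0,0.0,0.0,0.0
t2p005,9,4,18.11111111111111,0.0,0.0,0.0,0.0,2.0,0.0,0.0,64146.0,0.0,0.0,0.0
t2p006,9,4,18.11111111111111,1.0,0.0,0.0,0.0,2.0,0.0,0.0,16791.0,0.0,0.0,0.0
t2p007,9,4,18.11111111111111,1.0,0.0,0.0,2.0,3.0,1.0,1.0,66693.0,0.0,0.0,0.0
t2p008,9,4,18.11111111111111,1.0,0.0,0.0,0.0,3.0,0.0,0.0,71312.0,0.0,0.0,0.0
t3p000,6,5,18.0,1.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,1.0,0.0
t3p001,6,5,18.0,0.0,0.0,0.0,0.0,2.0,0.0,1.0,47224.0,0.0,0.0,0.0
t3p002,6,5,18.0,0.0,0.0,0.0,0.0,1.0,0.0,0.0,1109.0,0.0,1.0,0.0
t3p003,6,5,18.0,1.0,0.0,0.0,0.0,0.0,1.0,0.0,50598.0,0.0,0.0,1.0
t3p004,6,5,18.0,1.0,0.0,0.0,0.0,2.0,1.0,0.0,83725.0,0.0,0.0,1.0
t3p005,6,5,18.0,1.0,0.0,0.0,0.0,1.0,1.0,0.0,51171.0,0.0,0.0,0.0
t4p000,9,4,19.666666666666668,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
t4p001,9,4,19.666666666666668,0.0,0.0,0.0,0.0,3.0,0.0,0.0,1430.0,0.0,0.0,0.0
t4p002,9,4,19.666666666666668,1.0,0.0,0.0,0.0,2.0,0.0,0.0,31223.0,0.0,0.0,0.0
t4p003,9,4,19.666666666666668,1.0,0.0,0.0,0.0,3.0,1.0,0.0,52410.0,0.0,0.0,1.0
t4p004,9,4,19.666666666666668,1.0,0.0,0.0,0.0,4.0,0.0,1.0,80366.0,0.0,0.0,0.0
t4p005,9,4,19.666666666666668,1.0,0.0,0.0,0.0,4.0,0.0,0.0,72908.0,0.0,0.0,0.0
t4p006,9,4,19.666666666666668,2.0,0.0,0.0,1.0,2.0,1.0,0.0,10136.0,0.0,0.0,0.0
t4p007,9,4,19.666666666666668,0.0,0.0,0.0,0.0,2.0,0.0,0.0,85992.0,0.0,0.0,0.0
t4p008,9,4,19.666666666666668,0.0,0.0,0.0,0.0,2.0,0.0,0.0,47331.0,0.0,0.0,0.0
t5p000,6,5,15.333333333333334,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
t5p001,6,5,15.333333333333334,1.0,0.0,0.0,3.0,1.0,1.0,1.0,21011.0,0.0,0.0,1.0
t5p002,6,5,15.333333333333334,0.0,0.0,0.0,0.0,0.0,0.0,0.0,3496.0,0.0,0.0,0.0
t5p003,6,5,15.333333333333334,1.0,0.0,0.0,0.0,4.0,0.0,0.0,85687.0,0.0,0.0,0.0
t5p004,6,5,15.333333333333334,0.0,0.0,0.0,0.0,3.0,1.0,0.0,18455.0,0.0,0.0,0.0
t5p005,6,5,15.333333333333334,0.0,0.0,0.0,0.0,0.0,0.0,0.0,74964.0,0.0,0.0,0.0
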