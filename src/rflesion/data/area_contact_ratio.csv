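angle_deg,force_gf,mean,sd,n
0,2,1.46,,
0,4,2.23,,
0,6,2.28,,
0,10,2.53,,
0,15,2.45,,
0,20,2.35,,
0,30,2.32,,
0,40,2.31,,
30,2,2.74,,
30,4,2.91,,
30,6,3.0,,
30,10,3.89,,
30,15,2.6,,
30,20,1.97,,
30,30,3.45,,
30,40,2.73,,
45,2,1.83,,
45,4,2.84,,
45,6,1.94,,
45,10,2.07,,
45,15,2.03,,
45,20,2.54,,
45,30,2.38,,
45,40,2.04,,
60,2,1.95,,
60,4,2.63,,
60,6,2.51,,
60,10,2.08,,
60,15,2.09,,
60,20,2.66,,
60,30,2.76,,
60,40,3.1,,
90,2,3.86,,
90,4,4.22,,
90,6,3.04,,
90,10,3.18,,
90,15,2.34,,
90,20,3.08,,
90,30,3.14,,
90,40,2.99,,
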