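angle_deg,force_gf,mean,sd,n
0,2,1.98,0.3,6
0,4,1.9,0.14,6
0,6,2.5,0.32,6
0,10,3.43,0.53,6
0,15,3.74,0.4,6
0,20,4.09,0.43,6
0,30,4.1,0.21,6
0,40,4.76,0.36,6
30,2,1.7,0.23,6
30,4,2.02,0.36,6
30,6,2.23,0.28,6
30,10,3.43,0.43,6
30,15,3.4,0.62,6
30,20,4.16,0.55,6
30,30,4.26,0.58,6
30,40,5.54,0.42,6
45,2,1.92,0.39,6
45,4,2.14,0.2,6
45,6,2.49,0.22,6
45,10,3.04,0.45,6
45,15,3.46,0.77,6
45,20,3.78,0.54,6
45,30,5.56,0.48,6
45,40,5.75,0.57,6
60,2,2.2,0.4,6
60,4,2.31,0.32,6
60,6,3.1,0.66,6
60,10,3.8,0.45,6
60,15,4.76,0.65,6
60,20,4.45,0.56,6
60,30,5.48,0.6,6
60,40,5.68,0.47,6
90,2,3.68,0.38,6
90,4,4.16,0.47,6
90,6,4.25,0.33,6
90,10,4.49,0.38,6
90,15,5.89,0.61,6
90,20,5.8,0.5,6
90,30,6.31,0.68,6
90,40,7.53,0.33,6
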