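angle_deg,force_gf,mean,sd,n
0,2,16.67,1.63,6
0,4,24.17,4.14,6
0,6,24.05,3.46,6
0,10,35.54,1.59,6
0,15,37.81,2.87,6
0,20,36.1,3.18,6
0,30,38.04,6.07,6
0,40,44.1,3.5,6
30,2,16.46,3.0,6
30,4,21.58,2.94,6
30,6,23.81,1.4,6
30,10,37.35,3.88,6
30,15,34.23,3.98,6
30,20,28.9,6.62,6
30,30,40.6,6.78,6
30,40,40.33,6.9,6
45,2,12.93,1.13,6
45,4,19.98,0.68,6
45,6,19.76,3.06,6
45,10,21.7,2.24,6
45,15,24.01,0.65,6
45,20,32.59,4.58,6
45,30,35.37,5.39,6
45,40,39.38,5.82,6
60,2,9.05,1.79,6
60,4,19.07,3.43,6
60,6,20.52,2.23,6
60,10,20.99,0.79,6
60,15,23.26,3.55,6
60,20,30.41,6.69,6
60,30,33.44,3.79,6
60,40,41.87,5.68,6
90,2,13.28,1.49,6
90,4,18.53,1.46,6
90,6,17.09,3.1,6
90,10,21.89,1.9,6
90,15,19.55,0.87,6
90,20,22.78,3.84,6
90,30,29.85,1.46,6
90,40,37.62,7.27,6
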