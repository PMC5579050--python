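points_lo,points_hi,r3_lo,r3_hi,r5_lo,r5_hi,r8_lo,r8_hi
-16,-14,0.12,0.15,0.25,0.30,0.53,0.63
-13,-11,0.16,0.19,0.33,0.39,0.69,0.82
-10,-8,0.21,0.25,0.43,0.51,0.90,1.07
-7,-5,0.27,0.32,0.56,0.66,1.17,1.39
-4,-2,0.35,0.42,0.72,0.86,1.51,1.80
-1,1,0.46,0.54,0.94,1.12,1.96,2.33
2,4,0.59,0.71,1.22,1.45,2.54,3.01
5,7,0.77,0.92,1.58,1.88,3.28,3.90
8,10,1.00,1.19,2.05,2.44,4.25,5.04
11,13,1.30,1.54,2.65,3.15,5.48,6.49
14,16,1.68,2.00,3.43,4.08,7.06,8.35
17,19,2.18,2.59,4.44,5.26,9.08,10.71
20,22,2.82,3.35,5.73,6.78,11.63,13.69
23,25,3.65,4.33,7.38,8.72,14.84,17.41
26,28,4.72,5.59,9.48,11.18,18.83,22.00
29,31,6.09,7.20,12.13,14.28,23.75,27.59
32,34,7.84,9.26,15.47,18.14,29.69,34.25
35,37,10.06,11.86,19.62,22.89,36.72,42.01
38,39,12.87,13.95,24.70,26.62,44.82,47.73
40,41,15.12,16.38,28.66,30.83,50.73,
42,43,17.74,19.19,33.11,35.52,56.95,60.14
44,45,20.74,22.40,38.05,40.70,63.34,66.55
46,47,24.18,26.07,43.46,46.32,69.73,72.85
48,49,28.08,30.20,49.28,52.32,75.89,78.83
50,51,32.46,34.83,55.44,58.60,81.62,84.25
52,53,37.32,39.94,61.80,65.01,86.69,88.93
54,55,42.67,45.50,68.20,71.36,90.94,92.72
56,57,48.44,51.46,74.44,77.43,94.27,95.58
58,59,54.55,57.70,80.30,83.01,96.68,97.56
60,61,60.90,64.10,85.54,87.88,98.26,98.80
62,63,67.31,70.47,90.00,91.90,99.20,99.48
64,65,73.58,76.60,93.55,94.98,99.68,99.81
66,67,79.50,82.26,96.18,97.16,99.89,99.94
68,69,84.85,87.24,97.95,98.56,99.97,99.99
70,71,89.43,91.38,99.02,99.36,99.99,100.00
72,73,93.11,94.60,99.60,99.76,100.00,100.00
74,76,95.86,97.75,99.86,99.96,100.00,100.00
77,79,98.40,99.28,99.98,100.00,100.00,100.00
80,97,99.54,100.00,100.00,100.00,100.00,100.00
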