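subject,age,sex,years_post_stroke,stroke_hemisphere,fm,walking_speed_m_min,fa_asymmetry,fcr_paretic,lesion_volume_mm3,lesion_overlap_mm3
1,60,M,4.5,L,34,89.75,0.08,1.11,148248,320
2,56,M,4.7,L,25,40.95,0.10,1.42,2016,0
3,64,M,1.8,R,26,45.11,0.04,1.21,608,392
4,74,F,1.8,L,15,4.75,0.12,1.96,3752,176
5,77,F,2.8,L,15,9.68,0.24,1.55,2432,112
6,65,M,1.3,R,29,35.00,0.17,2.05,2392,376
7,73,M,2.7,R,15,5.40,0.43,2.63,355960,440
8,79,M,2.0,L,34,76.90,0.00,0.27,727,232
9,70,M,1.0,R,20,42.90,0.13,1.62,6496,0
10,66,M,4.6,R,29,25.60,0.06,1.13,45736,6220
11,56,M,11.3,L,32,57.10,0.03,0.94,108630,1308
12,57,F,4.0,R,12,11.30,0.25,2.50,26162,235
13,72,M,4.9,R,25,49.00,0.12,0.55,22204,0
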