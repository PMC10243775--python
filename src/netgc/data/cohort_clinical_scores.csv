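patient,visit,lesion_hemisphere,acute_nihss,nihss,mrs,barthel,moca,hvlt,verbal_fluency,trail_making,pegboard,sdmt,favourable_outcome
1,1,left,4,0,1,100,24,-2.000,-0.867,-1.760,-1.480,-1.410,
1,2,left,4,0,1,100,26,0.600,0.000,-0.120,-2.830,-0.790,
1,3,left,4,0,1,100,27,-0.600,0.333,0.200,-1.030,-1.210,yes
2,1,left,0,0,1,100,26,-2.550,2.100,0.200,-3.250,0.770,
2,2,left,0,0,1,100,27,-1.350,2.100,0.660,-4.140,0.530,
2,3,left,0,0,0,100,28,-0.350,3.000,0.540,-3.620,0.300,yes
3,1,right,3,3,1,100,21,-2.300,-0.867,-2.140,-5.030,-0.560,
3,2,right,3,0,1,100,20,-2.450,-1.067,-1.200,-8.360,-1.340,
3,3,right,3,0,1,100,20,-2.200,-1.200,-1.080,-3.260,-1.730,no
4,1,right,2,2,1,100,24,-2.600,-1.633,-2.400,-15.680,-1.800,
4,2,right,2,0,0,100,29,-1.900,-0.667,-1.400,-0.380,-1.030,
4,3,right,2,0,0,100,27,,,,,,no
5,1,right,3,0,1,100,26,-1.900,-0.233,-0.960,-2.090,-1.100,
5,2,right,3,0,0,100,27,-2.250,-0.330,0.000,-0.780,-1.310,
5,3,right,3,0,0,100,29,-0.200,0.333,0.220,0.850,-1.000,yes
6,1,right,1,1,0,100,28,-1.200,-0.333,-1.080,-7.810,-0.720,
6,2,right,1,1,1,100,30,-1.750,0.133,-0.940,-3.200,-0.800,
6,3,right,1,1,1,100,29,0.200,-0.667,-0.520,3.540,-1.030,no
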