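specimen_id,piece_index,morphotype,part,length_um
Dip-00655,1,morphotype 1,abdomen,1777.074
Dip-00655,1,morphotype 1,thorax+head,1013.289
Dip-00655,1,morphotype 1,total,2679.723
Dip-00655,2,morphotype 1,abdomen,2484.743
Dip-00655,2,morphotype 1,thorax+head,1614.781
Dip-00655,2,morphotype 1,total,3842.338
Dip-00652,,morphotype 3,thorax+head,362.857
Dip-00652,,morphotype 3,abdomen,527.673
Dip-00652,,morphotype 3,total,826.356
Dip-00653,,morphotype 1,abdomen,2420.659
Dip-00653,,morphotype 1,thorax+head,1779.554
Dip-00653,,morphotype 1,total,3919.83
GPIH-1851DN,,morphotype 1,abdomen,3021.056
GPIH-1851DN,,morphotype 1,thorax+head,2266.877
GPIH-1851DN,,morphotype 1,total,5059.427
Dip-00641,,morphotype 1,abdomen,2340.723
Dip-00641,,morphotype 1,thorax+head,1624.223
Dip-00641,,morphotype 1,total,3876.262
Dip-00650,,morphotype 3,thorax+head,320.106
Dip-00650,,morphotype 3,abdomen,645.888
Dip-00650,,morphotype 3,total,864.21
Dip-00660,,morphotype 1,abdomen,2935.409
Dip-00660,,morphotype 1,thorax+head,1924.388
Dip-00660,,morphotype 1,total,4238.969
Dip-00661,,morphotype 1,abdomen,3647.714
Dip-00661,,morphotype 1,thorax+head,2220.334
Dip-00661,,morphotype 1,total,5861.01
Dip-00657,,morphotype 1,abdomen,2310.204
Dip-00657,,morphotype 1,thorax+head,1453.298
Dip-00657,,morphotype 1,total,3835.301
GPIH-N-7095.,,morphotype 1,abdomen,2154.926
GPIH-N-7095.,,morphotype 1,thorax+head,1710.244
GPIH-N-7095.,,morphotype 1,total,3761.555
Dip-00659,,morphotype 1,abdomen,2466.357
Dip-00659,,morphotype 1,thorax+head,1697.196
Dip-00659,,morphotype 1,total,3744.385
Dip-00651,,morphotype 1,abdomen,2187.597
Dip-00651,,morphotype 1,thorax+head,1543.324
Dip-00651,,morphotype 1,total,3343.985
AKBS-00071,,morphotype 1,abdomen,2490.055
AKBS-00071,,morphotype 1,thorax+head,1784.352
AKBS-00071,,morphotype 1,total,3630.701
PED-4395,,morphotype 1,abdomen,2081.768
PED-4395,,morphotype 1,thorax+head,1561.697
PED-4395,,morphotype 1,total,3528.726
PED-4866,,morphotype 2,thorax+head,2596.66
PED-4866,,morphotype 2,abdomen,3041.19
PED-4866,,morphotype 2,total,5379.843
PED-4998,,morphotype 1,abdomen,2882.949
PED-4998,,morphotype 1,thorax+head,2174.641
PED-4998,,morphotype 1,total,4811.619
GPIH-L-7514,,morphotype 2,thorax+head,1826.663
GPIH-L-7514,,morphotype 2,abdomen,2936.171
GPIH-L-7514,,morphotype 2,total,4858.746
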