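term,chi2,chi2_df,cfi,rmsea,srmr
intercept,-23.94201,3.28519,-0.53129,0.13285,0.05279
mlr,6.72418,0.45189,-0.21041,0.01536,
dwls,5.84976,-0.68404,0.19662,-0.03062,0.03774
wlsmv,-4.68805,-0.27096,0.06079,-0.00865,
indicators,11.08965,-0.04753,0.04016,-0.00235,0.00278
options,-7.16670,-0.35058,0.12387,-0.00896,-0.00963
options2,0.72250,0.03496,-0.00936,0.00098,0.00084
asymmetric,-0.27294,0.02331,-0.04904,-0.00024,-0.00115
loading,-25.73792,-3.58376,4.12967,-0.08865,0.02653
loading2,20.41717,2.96247,-2.75074,0.05766,-0.09506
n,0.00906,0.45022,2.27580,-0.12606,-0.05619
n2,1.20211,-0.15723,-0.82698,0.04331,0.01882
factors,-12.26618,-0.19792,-0.32211,-0.00594,0.01323
mlr:indicators,-0.49485,-0.01090,0.00247,-0.00041,
mlr:options,0.17085,0.00216,0.00384,0.00005,
mlr:options2,-0.02131,-0.00052,-0.00024,-0.00001,
mlr:asymmetric,-2.71568,-0.08311,-0.00135,-0.00225,
mlr:loading,-7.76460,-0.99175,0.45378,-0.03246,
mlr:loading2,-2.61117,0.42949,-0.31994,0.01556,
mlr:n,-3.93101,-0.26550,0.09707,-0.00768,
mlr:n2,1.45709,0.09907,-0.03794,0.00311,
mlr:factors,2.71283,0.11781,-0.00868,0.00304,
dwls:indicators,-2.43747,0.00544,0.00158,-0.00038,-0.00022
dwls:options,-0.39327,-0.02550,-0.00440,-0.00033,-0.00758
dwls:options2,0.02110,0.00195,0.00034,0.00003,0.00058
dwls:asymmetric,-3.01669,-0.09613,0.00452,-0.00244,0.00140
dwls:loading,-41.99689,-1.36226,-0.30944,-0.05998,-0.00280
dwls:loading2,16.73726,0.48895,0.18350,0.02118,-0.00311
dwls:n,-2.10846,-0.11430,-0.11629,0.02896,-0.02165
dwls:n2,0.75628,0.04419,0.04250,-0.00982,0.00756
dwls:factors,16.86537,0.64662,-0.01075,0.02281,0.00330
wlsmv:indicators,-0.60239,-0.00413,0.00097,-0.00029,
wlsmv:options,0.63654,0.01440,-0.00270,0.00054,
wlsmv:options2,-0.05539,-0.00115,0.00022,-0.00004,
wlsmv:asymmetric,-2.91980,-0.09484,0.00368,-0.00256,
wlsmv:loading,10.29574,0.24493,-0.06415,0.00577,
wlsmv:loading2,-15.70961,-0.45035,0.03405,-0.01194,
wlsmv:n,3.01133,0.05021,-0.04314,0.00682,
wlsmv:n2,-1.16888,-0.01938,0.01545,-0.00250,
wlsmv:factors,3.90897,0.15706,-0.00697,0.00452,
indicators:options,-0.25997,-0.00776,0.00002,-0.00033,-0.00019
indicators:options2,0.02789,0.00081,-0.00003,0.00004,0.00002
indicators:asymmetric,0.17890,0.00040,0.00034,0.00002,0.00003
indicators:loading,-4.80064,-0.04388,-0.10488,-0.00698,-0.00316
indicators:loading2,3.83154,0.04484,0.07017,0.00652,0.00190
indicators:n,-1.04664,0.00016,-0.01404,0.00655,-0.00160
indicators:n2,0.38895,0.00157,0.00500,-0.00224,0.00058
indicators:factors,0.64889,-0.01164,0.00234,-0.00030,0.00003
options:asymmetric,0.47743,0.01356,-0.00319,0.00043,0.00061
options:loading,22.43204,1.53987,-0.33800,0.04504,0.01794
options:loading2,-19.13312,-1.33866,0.23297,-0.03818,-0.01639
options:n,2.42094,-0.20111,-0.00951,-0.00561,0.01125
options:n2,-1.16974,0.07428,0.00109,0.00208,-0.00388
options:factors,1.18404,0.04887,0.00555,0.00098,0.00068
options2:asymmetric,-0.04690,-0.00122,0.00031,-0.00005,-0.00006
options2:loading,-2.12451,-0.14685,0.02682,-0.00451,-0.00166
options2:loading2,1.79085,0.12730,-0.01863,0.00381,0.00151
options2:n,-0.40475,0.01424,0.00006,0.00030,-0.00097
options2:n2,0.17973,-0.00524,0.00020,-0.00011,0.00034
options2:factors,-0.10687,-0.00463,-0.00039,-0.00010,-0.00005
asymmetric:loading,3.71952,0.27558,0.11280,0.01327,0.00844
asymmetric:loading2,-1.17710,-0.18396,-0.07174,-0.00937,-0.00713
asymmetric:n,0.29781,-0.00253,0.02437,-0.00219,-0.00393
asymmetric:n2,-0.16484,-0.00346,-0.00870,0.00072,0.00138
asymmetric:factors,-0.81043,-0.03425,-0.00208,-0.00101,-0.00028
loading:n,16.43214,0.03858,-5.87140,0.01187,-0.04098
loading:n2,-8.22119,-0.08583,2.14448,-0.00411,0.01586
loading:factors,1.82103,0.21559,0.65988,0.02703,-0.01793
loading2:n,-15.03742,-0.14310,3.87122,0.00022,0.06458
loading2:n2,7.54665,0.12608,-1.41187,0.00015,-0.02336
loading2:factors,5.02726,0.03351,-0.43878,-0.01413,0.04983
n:factors,0.39375,0.08076,0.09529,-0.00988,-0.02326
n2:factors,-0.26943,-0.03848,-0.03378,0.00320,0.00784
factors:correlated,-2.51728,-0.05765,0.00487,-0.00223,-0.00481
r_squared,0.970,0.810,0.902,0.903,0.963
n_cells,1296,1296,1296,1296,648
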