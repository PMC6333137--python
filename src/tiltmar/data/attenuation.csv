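# Linear attenuation coefficients mu [1/cm] vs photon energy [keV].
# Compiled from NIST XCOM mass-attenuation tables (values rounded) times nominal
# densities: air 0.001205, water 1.00, adipose (ICRU-44) 0.95, soft_tissue
# (ICRU-44) 1.06, cortical bone
# (ICRU-44) 1.92, gypsum (CaSO4.2H2O) 2.32, aluminum 2.699, titanium 4.506,
# steel (316 stainless, Fe-dominated) 8.00, cerrobend (Bi/Pb/Sn/Cd 50/26.7/13.3/10,
# 9.4 g/cm3, K-edge structure near 88-91 keV retained) g/cm3.
material,energy_kev,mu_per_cm
air,10,6.170e-3
air,15,1.945e-3
air,20,9.374e-4
air,30,4.263e-4
air,40,2.994e-4
air,50,2.506e-4
air,60,2.259e-4
air,80,2.003e-4
air,100,1.857e-4
air,120,1.759e-4
air,150,1.634e-4
water,10,5.329
water,15,1.673
water,20,0.8096
water,30,0.3756
water,40,0.2683
water,50,0.2269
water,60,0.2059
water,80,0.1837
water,100,0.1707
water,120,0.1620
water,150,0.1505
soft_tissue,10,5.689
soft_tissue,15,1.795
soft_tissue,20,0.8697
soft_tissue,30,0.4010
soft_tissue,40,0.2846
soft_tissue,50,0.2398
soft_tissue,60,0.2171
soft_tissue,80,0.1932
soft_tissue,100,0.1795
soft_tissue,120,0.1707
soft_tissue,150,0.1582
adipose,10,2.523
adipose,15,0.940
adipose,20,0.539
adipose,30,0.287
adipose,40,0.227
adipose,50,0.204
adipose,60,0.191
adipose,80,0.174
adipose,100,0.163
adipose,120,0.155
adipose,150,0.145
bone,10,54.74
bone,15,17.34
bone,20,7.682
bone,30,2.556
bone,40,1.278
bone,50,0.8145
bone,60,0.6044
bone,80,0.4280
bone,100,0.3562
bone,120,0.3264
bone,150,0.2842
gypsum,10,41.80
gypsum,15,13.50
gypsum,20,6.010
gypsum,30,2.100
gypsum,40,1.123
gypsum,50,0.7830
gypsum,60,0.6290
gypsum,80,0.4910
gypsum,100,0.4310
gypsum,120,0.3980
gypsum,150,0.3600
aluminum,10,70.79
aluminum,15,21.47
aluminum,20,9.287
aluminum,30,3.044
aluminum,40,1.534
aluminum,50,0.9935
aluminum,60,0.7498
aluminum,80,0.5447
aluminum,100,0.4600
aluminum,120,0.4146
aluminum,150,0.3719
titanium,10,498.8
titanium,15,161.6
titanium,20,71.42
titanium,30,22.40
titanium,40,9.976
titanium,50,5.466
titanium,60,3.452
titanium,80,1.826
titanium,100,1.226
titanium,120,0.9643
titanium,150,0.7430
steel,10,1364.8
steel,15,456.6
steel,20,205.4
steel,30,65.41
steel,40,29.03
steel,50,15.66
steel,60,9.640
steel,80,4.762
steel,100,2.974
steel,120,2.166
steel,150,1.571
cerrobend,10,1259.6
cerrobend,15,898.6
cerrobend,20,649.5
cerrobend,30,227.5
cerrobend,40,108.1
cerrobend,50,60.44
cerrobend,60,37.69
cerrobend,80,18.24
cerrobend,100,39.10
cerrobend,120,24.53
cerrobend,150,14.76
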