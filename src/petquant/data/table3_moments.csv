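family,segmentation,statistic,mean_wt,sd_wt,mean_mut,sd_mut
suv,mim,mean,5.70,1.82,6.91,2.46
suv,mim,peak,6.56,2.61,8.29,4.04
suv,mim,max,8.63,3.74,11.79,5.17
suv,hermes,mean,5.63,1.46,6.65,1.68
suv,hermes,peak,7.09,2.97,9.21,4.33
suv,hermes,max,8.63,3.74,11.79,5.17
suv_pvec,mim,mean,7.13,2.62,8.94,3.26
suv_pvec,mim,peak,7.63,2.92,9.79,3.93
suv_pvec,mim,max,9.44,3.89,13.09,4.96
suv_pvec,hermes,mean,7.00,2.12,8.37,1.86
suv_pvec,hermes,peak,8.18,3.17,10.53,3.95
suv_pvec,hermes,max,9.33,3.66,12.63,4.68
suv_pvec_time,mim,mean,5.98,2.39,7.74,3.18
suv_pvec_time,mim,peak,6.42,2.74,8.44,3.66
suv_pvec_time,mim,max,7.92,3.57,11.19,4.46
suv_pvec_time,hermes,mean,5.87,2.14,7.22,1.92
suv_pvec_time,hermes,peak,6.88,3.04,8.99,3.44
suv_pvec_time,hermes,max,7.83,3.45,10.77,4.05
suvtlr_pvec,mim,mean,2.64,1.11,3.54,1.53
suvtlr_pvec,mim,peak,2.81,1.20,3.92,1.91
suvtlr_pvec,mim,max,3.51,1.66,5.28,2.61
suvtlr_pvec,hermes,mean,2.62,1.08,3.35,1.16
suvtlr_pvec,hermes,peak,3.06,1.43,4.27,2.16
suvtlr_pvec,hermes,max,3.49,1.63,5.12,2.56
sur_time,mim,mean,2.10,0.89,2.77,0.83
sur_time,mim,peak,2.43,1.24,3.30,1.43
sur_time,mim,max,3.20,1.74,4.66,1.81
sur_time,hermes,mean,2.06,0.81,2.70,0.67
sur_time,hermes,peak,2.63,1.40,3.65,1.53
sur_time,hermes,max,3.20,1.74,4.66,1.81
sur_pvec_time,mim,mean,2.60,1.17,3.59,1.15
sur_pvec_time,mim,peak,2.80,1.35,3.93,1.43
sur_pvec_time,mim,max,3.47,1.79,5.23,1.79
sur_pvec_time,hermes,mean,2.55,1.07,3.42,0.85
sur_pvec_time,hermes,peak,3.01,1.52,4.23,1.46
sur_pvec_time,hermes,max,3.43,1.75,5.06,1.72
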