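cohort,study_label,regimen,parameter,predicted,observed,printed_mfe
adult_dev,Amini 2010,single_400,auc_0_inf,33.99,26.18,1.30
adult_dev,Amini 2010,single_400,cmax,3.08,3.41,0.90
adult_dev,Amini 2010,single_400,tmax,2.50,3.02,0.83
adult_dev,Jalalizadeh 2007,single_400,auc_0_inf,33.99,29.09,1.17
adult_dev,Jalalizadeh 2007,single_400,cmax,3.08,3.33,0.92
adult_dev,Jalalizadeh 2007,single_400,tmax,2.50,3.13,0.80
adult_dev,Almeida 2006 reference,single_400,auc_0_inf,26.97,29.64,0.91
adult_dev,Almeida 2006 reference,single_400,cmax,2.50,2.82,0.89
adult_dev,Almeida 2006 reference,single_400,tmax,2.55,3.75,0.68
adult_dev,Almeida 2006 test,single_400,auc_0_inf,26.97,28.88,0.93
adult_dev,Almeida 2006 test,single_400,cmax,2.50,2.89,0.87
adult_dev,Almeida 2006 test,single_400,tmax,2.55,3.75,0.68
adult_dev,Blum 1994,single_400,auc_0_inf,26.97,38.95,0.69
adult_dev,Blum 1994,single_400,cmax,2.50,2.91,0.86
adult_dev,Blum 1994,single_400,tmax,2.55,3.15,0.81
adult_dev,KuKanich 2013,single_600,auc_0_inf,50.98,48.71,1.05
adult_dev,KuKanich 2013,single_600,cmax,4.62,4.85,0.95
adult_dev,KuKanich 2013,single_600,tmax,2.55,3.17,0.80
adult_dev,Toh 2014,single_600,auc_0_inf,50.98,51.88,0.98
adult_dev,Toh 2014,single_600,cmax,4.62,4.74,0.97
adult_dev,Toh 2014,single_600,tmax,2.55,1.46,1.75
adult_dev,Kang 2007,single_300,auc_0_inf,25.49,18.82,1.35
adult_dev,Kang 2007,single_300,cmax,2.31,1.92,1.20
adult_dev,Kang 2007,single_300,tmax,2.50,2.50,1.00
adult_eval,Gidal 1998-1,single_600,auc_0_inf,43.66,41.79,1.04
adult_eval,Gidal 1998-1,single_600,cmax,3.61,3.98,0.91
adult_eval,Gidal 1998-1,single_600,tmax,2.5,4.02,0.62
adult_eval,Gidal 1996,single_300,auc_0_inf,43.66,44,0.99
adult_eval,Gidal 1996,single_300,cmax,3.61,3.87,0.93
adult_eval,Gidal 1996,single_300,tmax,2.5,3.9,0.64
adult_eval,Park 2007 test,single_300,auc_0_inf,27.24,18.32,1.49
adult_eval,Park 2007 test,single_300,cmax,1.73,1.72,1.01
adult_eval,Park 2007 test,single_300,tmax,2.94,3,0.98
adult_eval,Park 2007 reference,single_300,auc_0_inf,27.24,17.72,1.54
adult_eval,Park 2007 reference,single_300,cmax,1.73,1.71,1.01
adult_eval,Park 2007 reference,single_300,tmax,2.94,2.50,1.08
adult_eval,Cho 2006,single_400,auc_0_inf,37.46,22.51,1.66
adult_eval,Cho 2006,single_400,cmax,2.83,2.7,1.05
adult_eval,Cho 2006,single_400,tmax,2.82,2.5,1.13
adult_eval,Cowles 2012,qd_600,auc_0_inf,79.8,62.929,1.27
adult_eval,Cowles 2012,qd_600,cmax,3.7,5.004,0.74
adult_eval,Cowles 2012,qd_600,tmax,5.28,7,0.75
adult_eval,Gidal 1998,tid_400,auc_0_inf,77.37,138.32,0.56
adult_eval,Gidal 1998,tid_400,cmax,4.75,5.26,0.90
adult_eval,Gidal 1998,tid_400,tmax,2.15,2.49,0.86
adult_eval,Eldon 1998,tid_400,auc_0_inf,77.37,208,0.37
adult_eval,Eldon 1998,tid_400,cmax,4.75,5.24,0.90
adult_eval,Eldon 1998,tid_400,tmax,2.15,2.03,1.06
adult_eval,Cowles 2012,bid_600_1200,auc_0_inf,100.69,141.301,0.71
adult_eval,Cowles 2012,bid_600_1200,cmax,9.73,8.92,1.09
adult_eval,Cowles 2012,bid_600_1200,tmax,6.63,6,1.11
adult_eval,Gordi 2008,bid_600_1200,auc_0_inf,120.69,144,0.84
adult_eval,Gordi 2008,bid_600_1200,cmax,9.73,6.997,1.40
adult_eval,Gordi 2008,bid_600_1200,tmax,6.63,6,1.11
adult_eval,Gordi 2008 b,bid_600_1200,auc_0_inf,120.69,144.6,0.83
adult_eval,Gordi 2008 b,bid_600_1200,cmax,9.73,6.537,1.49
adult_eval,Gordi 2008 b,bid_600_1200,tmax,6.63,6,1.11
adult_eval,Cowles 2012,bid_600,auc_0_inf,115.73,107.84,1.07
adult_eval,Cowles 2012,bid_600,cmax,4.61,6.229,0.74
adult_eval,Cowles 2012,bid_600,tmax,4.22,8,0.53
adult_eval,Gidal 1998,tid_1200,auc_0_inf,208.49,298.36,0.70
adult_eval,Gidal 1998,tid_1200,cmax,13.91,11.25,1.24
adult_eval,Gidal 1998,tid_1200,tmax,2.14,2,1.07
adult_eval,Gidal 1998,tid_1600,auc_0_inf,238.33,355.12,0.67
adult_eval,Gidal 1998,tid_1600,cmax,15.81,12.30,1.29
adult_eval,Gidal 1998,tid_1600,tmax,2.14,2,1.07
adult_eval,Gordi 2008,qd_1800,auc_0_inf,185.91,123,1.51
adult_eval,Gordi 2008,qd_1800,cmax,6.64,7.974,1.09
adult_eval,Gordi 2008,qd_1800,tmax,5.94,8,0.46
adult_eval,Swearingen 2018,qd_1800,auc_0_inf,185.91,105,1.91
adult_eval,Swearingen 2018,qd_1800,cmax,8.7,8.43,1.03
adult_eval,Swearingen 2018,qd_1800,tmax,5.94,7,0.53
adult_eval,Gordi 2008 b,qd_1800,auc_0_inf,200.35,133,1.51
adult_eval,Gordi 2008 b,qd_1800,cmax,8.7,9.585,0.91
adult_eval,Gordi 2008 b,qd_1800,tmax,5.94,8,0.46
adult_eval,Gidal 1998,tid_600,auc_0_inf,147.17,225.57,0.65
adult_eval,Gidal 1998,tid_600,cmax,8.10,7.65,1.06
adult_eval,Gidal 1998,tid_600,tmax,2.34,2,1.17
adult_eval,Gordi 2008,tid_600,auc_0_inf,160.71,141,1.14
adult_eval,Gordi 2008,tid_600,cmax,8.85,8.166,1.08
adult_eval,Gordi 2008,tid_600,tmax,8,8,1.00
adult_eval,Backonja 2011,tid_600,auc_0_inf,160.71,166,0.97
adult_eval,Backonja 2011,tid_600,cmax,8.85,9.07,0.98
adult_eval,Backonja 2011,tid_600,tmax,8,2.31,3.46
adult_eval,Gordi 2008 c,tid_600,auc_0_inf,133.33,136,0.98
adult_eval,Gordi 2008 c,tid_600,cmax,8.85,7.455,1.19
adult_eval,Gordi 2008 c,tid_600,tmax,8,14,0.57
adult_eval,Swearingen 2018,tid_600,auc_0_inf,160.71,164,0.98
adult_eval,Swearingen 2018,tid_600,cmax,8.85,9.26,0.96
adult_eval,Swearingen 2018,tid_600,tmax,16,16,1.00
ri_adult,Lal 2012 moderate,single_600,auc_0_inf,121.52,180,0.68
ri_adult,Lal 2012 moderate,single_600,cmax,4.08,5.77,0.71
ri_adult,Lal 2012 moderate,single_600,tmax,3.89,10,0.39
ri_adult,Blum 1994 mild,single_400,auc_0_inf,76.71,110,0.70
ri_adult,Blum 1994 mild,single_400,cmax,3.31,4.8,0.69
ri_adult,Blum 1994 mild,single_400,tmax,3.85,5.1,0.75
ri_adult,Blum 1994 severe,single_400,auc_0_inf,181.88,280,0.65
ri_adult,Blum 1994 severe,single_400,cmax,3.59,4.8,0.75
ri_adult,Blum 1994 severe,single_400,tmax,5.9,8.0,0.74
pediatric,Haig 2001 3-12y,single_10mgkg,auc_0_inf,44.55,36,1.24
pediatric,Haig 2001 3-12y,single_10mgkg,cmax,4.05,4.52,0.90
pediatric,Haig 2001 3-12y,single_10mgkg,tmax,2.46,2.52,0.98
pediatric,Tallian 2004,tid_5.7mgkg,auc_0_inf,25.89,14.7,1.76
pediatric,Tallian 2004,tid_5.7mgkg,cmax,3.63,2.6,1.40
pediatric,Tallian 2004,tid_5.7mgkg,tmax,2.13,1.6,1.33
pediatric,Haig 2001 1m-3y,single_10mgkg,auc_0_inf,40.69,25.6,1.59
pediatric,Haig 2001 1m-3y,single_10mgkg,cmax,4.34,3.74,1.60
pediatric,Haig 2001 1m-3y,single_10mgkg,tmax,2.17,2.14,1.01
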