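layers,neurons,bitrate_bpp,cr_percent,psnr_db,ssim,n_params
3,30,0.245,99.233,31.081,0.767,2011
3,50,0.653,97.959,32.205,0.804,5351
3,70,1.256,96.074,34.550,0.903,10291
3,90,2.055,93.579,35.637,0.923,16831
3,110,3.048,90.474,36.610,0.942,24971
3,130,4.237,86.759,37.862,0.960,34711
3,150,5.621,82.433,38.389,0.964,46051
3,170,7.201,77.497,38.626,0.965,58991
3,190,8.976,71.950,39.954,0.975,73531
3,210,10.946,65.793,39.553,0.974,89671
3,230,13.112,59.026,40.934,0.981,107411
4,30,0.359,98.878,29.008,0.627,2941
4,50,0.964,96.986,32.472,0.825,7901
4,70,1.863,94.178,34.814,0.902,15261
4,90,3.054,90.455,36.450,0.937,25021
4,110,4.539,85.817,37.251,0.951,37181
4,130,6.316,80.262,39.872,0.974,51741
4,150,8.386,73.793,41.887,0.984,68701
4,170,10.750,66.407,42.395,0.986,88061
4,190,13.406,58.107,42.738,0.988,109821
4,210,16.355,48.890,43.586,0.989,133981
4,230,19.597,38.758,44.335,0.991,160541
5,30,0.473,98.523,30.846,0.781,3871
5,50,1.276,96.013,32.469,0.799,10451
5,70,2.470,92.282,38.391,0.964,20231
5,90,4.054,87.331,38.456,0.963,33211
5,110,6.029,81.159,40.037,0.976,49391
5,130,8.395,73.766,41.990,0.985,68771
5,150,11.151,65.152,42.953,0.988,91351
5,170,14.298,55.318,42.284,0.986,117131
5,190,17.836,44.263,43.366,0.989,146111
5,210,21.764,31.987,44.676,0.991,178291
5,230,26.083,18.491,44.616,0.991,213671
6,30,0.586,98.169,30.077,0.774,4801
6,50,1.587,95.041,36.246,0.935,13001
6,70,3.076,90.387,39.529,0.974,25201
6,90,5.054,84.207,40.204,0.977,41401
6,110,7.520,76.501,41.779,0.984,61601
6,130,10.474,67.270,41.733,0.984,85801
6,150,13.916,56.512,43.195,0.988,114001
6,170,17.847,44.229,42.773,0.988,146201
6,190,22.266,30.420,44.301,0.991,182401
6,210,27.173,15.084,42.274,0.984,222601
6,230,32.568,-1.777,43.441,0.988,266801
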