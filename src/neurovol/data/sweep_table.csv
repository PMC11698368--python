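nc,scale,neurons,bitrate_bpp,cr_percent,psnr_db,ssim,n_params,gpu_mem_gb
4,1/2,30,0.775,97.578,33.885,0.885,6348,1.366
4,1/2,50,1.183,96.304,35.211,0.915,9688,1.395
4,1/2,70,1.786,94.420,36.853,0.947,14628,1.426
4,1/2,90,2.584,91.925,37.682,0.961,21168,1.456
4,1/2,110,3.578,88.820,38.547,0.969,29308,1.484
4,1/2,130,4.767,85.104,38.968,0.972,39048,1.512
4,1/2,150,6.151,80.779,38.867,0.974,50388,1.540
4,1/2,170,7.730,75.842,39.419,0.973,63328,1.570
4,1/2,190,9.505,70.296,39.603,0.976,77868,1.599
4,1/2,210,11.476,64.139,39.319,0.970,94008,1.629
4,1/2,230,13.641,57.372,39.665,0.976,111748,1.661
4,1/4,30,1.520,95.250,33.221,0.858,12452,1.319
4,1/4,50,1.928,93.976,33.985,0.892,15792,1.322
4,1/4,70,2.531,92.091,34.503,0.916,20732,1.331
4,1/4,90,3.329,89.597,34.789,0.921,27272,1.335
4,1/4,110,4.323,86.491,34.753,0.915,35412,1.333
4,1/4,130,5.512,82.776,34.825,0.921,45152,1.349
4,1/4,150,6.896,78.450,35.080,0.923,56492,1.348
4,1/4,170,8.476,73.514,35.001,0.924,69432,1.347
4,1/4,190,10.250,67.967,34.977,0.919,83972,1.347
4,1/4,210,12.221,61.810,35.300,0.927,100112,1.354
4,1/4,230,14.386,55.043,35.393,0.922,117852,1.355
4,1/8,30,7.481,76.622,40.991,0.977,61284,1.313
4,1/8,50,7.889,75.348,36.212,0.909,64624,1.314
4,1/8,70,8.492,73.463,40.873,0.977,69564,1.312
4,1/8,90,9.290,70.969,38.934,0.965,76104,1.315
4,1/8,110,10.284,67.863,40.995,0.979,84244,1.319
4,1/8,130,11.473,64.148,40.799,0.978,93984,1.316
4,1/8,150,12.857,59.822,40.150,0.975,105324,1.318
4,1/8,170,14.437,54.886,39.587,0.974,118264,1.316
4,1/8,190,16.211,49.339,39.866,0.973,132804,1.318
4,1/8,210,18.182,43.182,38.954,0.966,148944,1.317
4,1/8,230,20.347,36.415,39.094,0.960,166684,1.319
8,1/2,30,1.688,94.727,32.829,0.825,13824,1.330
8,1/2,50,2.095,93.452,36.009,0.922,17164,1.360
8,1/2,70,2.698,91.568,37.112,0.945,22104,1.387
8,1/2,90,3.497,89.073,38.502,0.964,28644,1.422
8,1/2,110,4.490,85.968,39.373,0.975,36784,1.451
8,1/2,130,5.679,82.253,39.127,0.974,46524,1.479
8,1/2,150,7.063,77.927,39.365,0.971,57864,1.506
8,1/2,170,8.643,72.990,41.106,0.982,70804,1.537
8,1/2,190,10.418,67.444,40.133,0.979,85344,1.562
8,1/2,210,12.388,61.287,38.495,0.976,101484,1.595
8,1/2,230,14.554,54.520,40.149,0.976,119224,1.625
8,1/4,30,3.171,90.091,35.348,0.886,25976,1.277
8,1/4,50,3.579,88.817,36.051,0.917,29316,1.281
8,1/4,70,4.182,86.932,37.443,0.941,34256,1.289
8,1/4,90,4.980,84.438,36.178,0.935,40796,1.291
8,1/4,110,5.974,81.332,38.016,0.948,48936,1.295
8,1/4,130,7.163,77.617,37.564,0.946,58676,1.307
8,1/4,150,8.547,73.291,38.021,0.948,70016,1.307
8,1/4,170,10.126,68.355,36.991,0.944,82956,1.307
8,1/4,190,11.901,62.808,38.424,0.950,97496,1.310
8,1/4,210,13.872,56.651,36.755,0.942,113636,1.311
8,1/4,230,16.037,49.884,36.696,0.942,131376,1.319
8,1/8,30,15.038,53.006,45.056,0.990,123192,1.273
8,1/8,50,15.446,51.732,44.628,0.989,126532,1.272
8,1/8,70,16.049,49.847,45.004,0.990,131472,1.276
8,1/8,90,16.847,47.353,44.226,0.987,138012,1.272
8,1/8,110,17.841,44.247,45.528,0.992,146152,1.277
8,1/8,130,19.030,40.532,43.596,0.985,155892,1.276
8,1/8,150,20.414,36.206,44.410,0.990,167232,1.276
8,1/8,170,21.994,31.270,43.539,0.986,180172,1.276
8,1/8,190,23.769,25.723,43.650,0.988,194712,1.277
8,1/8,210,25.739,19.566,42.061,0.981,210852,1.277
8,1/8,230,27.904,12.799,41.435,0.978,228592,1.275
16,1/2,30,5.095,84.079,34.469,0.858,41736,1.366
16,1/2,50,5.502,82.805,37.843,0.947,45076,1.396
16,1/2,70,6.105,80.920,39.609,0.965,50016,1.424
16,1/2,90,6.904,78.426,39.634,0.967,56556,1.457
16,1/2,110,7.897,75.320,40.585,0.979,64696,1.486
16,1/2,130,9.086,71.605,38.699,0.975,74436,1.514
16,1/2,150,10.471,67.279,41.600,0.982,85776,1.546
16,1/2,170,12.050,62.343,39.853,0.969,98716,1.568
16,1/2,190,13.825,56.796,41.416,0.981,113256,1.601
16,1/2,210,15.795,50.639,41.327,0.977,129396,1.632
16,1/2,230,17.961,43.872,39.053,0.977,147136,1.660
16,1/4,30,8.055,74.829,35.132,0.891,65984,1.272
16,1/4,50,8.462,73.555,38.964,0.941,69324,1.279
16,1/4,70,9.065,71.671,40.981,0.965,74264,1.290
16,1/4,90,9.864,69.176,40.182,0.965,80804,1.289
16,1/4,110,10.857,66.071,40.705,0.969,88944,1.292
16,1/4,130,12.046,62.355,42.462,0.979,98684,1.298
16,1/4,150,13.431,58.029,42.580,0.981,110024,1.307
16,1/4,170,15.010,53.093,41.079,0.970,122964,1.308
16,1/4,190,16.785,47.546,42.322,0.979,137504,1.306
16,1/4,210,18.755,41.389,41.177,0.974,153644,1.311
16,1/4,230,20.921,34.622,41.987,0.979,171384,1.313
16,1/8,30,31.734,0.830,49.798,0.998,259968,1.270
16,1/8,50,32.142,-0.444,48.750,0.996,263308,1.271
16,1/8,70,32.745,-2.328,48.238,0.995,268248,1.271
16,1/8,90,33.543,-4.823,48.497,0.997,274788,1.271
16,1/8,110,34.537,-7.928,46.755,0.993,282928,1.280
16,1/8,130,35.726,-11.644,48.436,0.997,292668,1.275
16,1/8,150,37.110,-15.970,50.539,0.999,304008,1.277
16,1/8,170,38.690,-20.906,48.897,0.996,316948,1.273
16,1/8,190,40.465,-26.453,48.730,0.997,331488,1.275
16,1/8,210,42.435,-32.610,46.971,0.994,347628,1.277
16,1/8,230,44.601,-39.377,47.476,0.996,365368,1.277
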