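blue,red,white,far_red,sucrose,n,mean_shoot_length,se_shoot_length,mean_root_length,se_root_length,mean_node_number,se_node_number,mean_shoot_number,se_shoot_number,mean_canopy_area,se_canopy_area
25,0,25,0,1,4,38.77,8.101,108.87,10.097,8.50,0.645,1.00,0.000,2309.42,314.907
25,0,25,0,3,4,32.44,7.036,42.47,29.857,8.00,0.408,2.25,0.479,2028.24,598.380
25,0,25,0,6,4,63.26,16.667,117.06,20.197,8.00,0.408,2.25,0.479,1885.75,385.882
50,0,0,0,1,4,32.94,2.406,26.45,23.515,7.25,0.750,1.00,0.000,1848.11,214.644
50,0,0,0,3,4,44.35,20.174,24.56,15.198,7.25,1.601,1.50,0.500,1495.87,757.315
50,0,0,0,6,4,39.03,10.839,142.17,45.483,7.50,0.866,1.25,0.250,1589.48,578.975
50,0,50,0,1,4,31.20,5.443,151.40,35.982,8.25,0.629,1.00,0.000,1717.80,582.898
50,0,50,0,3,4,40.91,13.542,82.77,17.954,8.50,0.500,1.25,0.250,1802.86,390.860
50,0,50,0,6,4,53.83,13.807,112.46,26.505,9.00,0.707,1.75,0.479,1880.05,744.967
100,0,0,0,1,4,23.43,2.634,0.00,0.000,5.75,0.479,1.25,0.250,493.01,111.615
100,0,0,0,3,4,22.95,2.991,15.04,8.855,6.75,0.479,1.00,0.000,650.45,126.813
100,0,0,0,6,4,33.42,11.272,102.47,60.796,6.50,0.500,2.00,0.577,890.63,444.374
12.5,12.5,12.5,12.5,1,4,43.13,9.839,97.61,34.009,7.25,0.479,1.50,0.289,2442.35,506.213
12.5,12.5,12.5,12.5,3,4,59.60,10.319,89.45,31.042,7.75,0.854,1.75,0.250,3193.41,888.482
12.5,12.5,12.5,12.5,6,4,64.51,38.597,63.48,34.099,8.25,2.016,1.75,0.479,2594.11,1648.261
37.5,12.5,0,0,1,4,47.40,11.309,63.68,24.567,7.00,0.816,1.50,0.289,1519.41,345.197
37.5,12.5,0,0,3,4,66.39,16.880,136.61,28.052,8.00,1.080,2.25,0.629,2177.63,519.451
37.5,12.5,0,0,6,4,38.41,5.652,100.51,37.320,7.75,0.479,1.50,0.289,1698.48,448.503
16.69,16.69,0,16.69,1,4,106.24,35.988,127.38,40.798,8.00,0.707,1.25,0.250,3350.76,789.191
16.69,16.69,0,16.69,3,4,142.22,36.056,101.97,41.471,9.75,0.750,2.50,0.866,4355.61,1395.277
16.69,16.69,0,16.69,6,4,38.89,11.084,46.67,29.388,6.75,0.854,1.25,0.250,1360.77,155.798
25,25,0,0,1,4,57.72,14.566,149.92,35.873,8.75,1.181,1.00,0.000,3776.96,1017.968
25,25,0,0,3,4,56.83,32.880,105.16,44.817,7.50,0.645,1.75,0.250,1737.36,1056.285
25,25,0,0,6,4,61.38,9.666,38.72,23.529,8.25,0.946,2.00,0.408,1216.37,114.887
25,25,25,25,1,4,87.11,22.707,134.47,48.218,8.75,0.854,1.75,0.250,6340.05,1284.607
25,25,25,25,3,4,56.06,12.648,72.80,36.452,9.25,0.250,1.00,0.000,3117.44,887.353
25,25,25,25,6,4,59.93,24.137,146.00,54.432,7.00,0.707,1.25,0.250,1829.20,645.785
75,25,0,0,1,4,33.30,5.883,65.71,42.275,7.50,1.041,1.00,0.000,2560.02,620.724
75,25,0,0,3,4,103.74,44.839,112.05,16.975,10.50,2.021,2.00,0.408,3964.16,1336.336
75,25,0,0,6,4,41.43,1.379,29.16,13.225,7.50,0.645,1.25,0.250,813.38,188.339
33.33,33.33,0,33.33,1,4,36.42,6.816,150.89,51.445,8.75,0.854,1.25,0.250,2091.81,525.087
33.33,33.33,0,33.33,3,4,98.40,44.716,477.10,287.094,11.50,2.901,1.00,0.000,2483.71,627.011
33.33,33.33,0,33.33,6,4,85.94,16.989,147.32,7.069,9.25,0.854,1.75,0.250,7136.78,1770.492
12.5,37.5,0,0,1,4,49.05,14.862,120.84,70.678,7.75,0.854,1.25,0.250,3232.08,1237.421
12.5,37.5,0,0,3,4,32.11,3.359,10.84,10.841,7.00,0.000,2.00,0.408,2505.37,374.173
12.5,37.5,0,0,6,4,50.48,11.078,122.62,37.803,8.25,0.479,2.25,0.946,1992.30,318.378
0,50,0,0,1,4,77.72,11.483,97.43,36.702,8.25,0.479,1.25,0.250,2500.70,678.427
0,50,0,0,3,4,99.81,31.278,158.00,58.672,7.75,0.946,1.75,0.479,3148.87,1255.456
0,50,0,0,6,4,46.90,1.499,35.98,20.840,8.50,0.289,1.50,0.289,1383.03,349.575
50,50,0,0,1,4,29.51,6.815,77.13,45.344,8.50,0.866,1.25,0.250,2447.43,737.653
50,50,0,0,3,4,68.50,16.044,73.50,26.470,8.75,0.629,2.25,0.479,13061.97,10839.642
50,50,0,0,6,4,55.40,24.082,29.79,29.794,9.00,0.707,2.00,0.408,1963.27,1336.004
0,50,25,0,1,4,63.01,11.807,87.61,55.464,9.00,0.707,1.50,0.289,2763.95,630.766
0,50,25,0,3,4,130.47,48.757,152.19,40.475,9.75,1.181,1.25,0.250,6939.43,2672.142
0,50,25,0,6,4,91.80,61.557,132.78,92.911,9.50,1.555,1.75,0.750,3000.23,1620.640
0,50,50,0,1,4,55.39,6.538,47.25,33.256,8.50,0.866,1.00,0.000,3123.43,594.904
0,50,50,0,3,4,73.49,16.669,159.08,45.374,9.50,0.645,1.75,0.479,5721.65,2203.448
0,50,50,0,6,4,78.72,27.594,91.01,34.488,8.50,0.500,1.50,0.289,3337.97,1156.575
25,75,0,0,1,4,49.02,6.926,121.57,43.981,8.50,0.866,1.00,0.000,3843.37,1073.415
25,75,0,0,3,4,78.73,21.040,79.38,39.101,10.50,1.190,1.00,0.000,6154.32,1303.577
25,75,0,0,6,4,55.71,17.245,75.76,27.694,9.00,0.408,1.25,0.250,2682.36,913.655
0,100,0,0,1,4,48.72,17.838,152.42,43.433,8.00,0.816,1.25,0.250,1642.67,438.197
0,100,0,0,3,4,101.24,32.678,207.67,41.674,7.50,0.289,1.25,0.250,1529.03,407.505
0,100,0,0,6,4,84.14,37.295,143.37,84.434,8.25,0.854,2.00,0.408,915.09,717.054
0,0,25,25,1,4,76.46,34.634,160.01,49.307,7.75,0.750,1.25,0.250,2370.35,467.347
0,0,25,25,3,4,154.68,51.228,171.42,17.863,8.50,1.041,1.50,0.289,2707.43,652.476
0,0,25,25,6,4,86.78,29.794,86.57,38.613,8.00,0.408,1.25,0.250,2782.91,1022.655
0,0,50,0,1,4,39.50,5.238,128.04,12.026,8.50,0.289,1.25,0.250,2751.85,906.598
0,0,50,0,3,4,35.85,6.990,74.44,27.158,8.25,0.479,1.50,0.289,1706.28,611.107
0,0,50,0,6,4,82.77,43.133,72.39,41.802,8.00,1.000,1.50,0.289,2249.33,1412.720
0,0,50,50,1,4,38.61,6.648,0.00,0.000,8.75,0.479,1.00,0.000,2169.51,649.210
0,0,50,50,3,4,136.64,29.794,148.92,23.789,8.75,0.629,2.00,0.408,3411.27,345.452
0,0,50,50,6,4,36.78,0.374,4.40,4.396,8.00,0.408,1.25,0.250,859.96,78.081
0,0,100,0,1,4,27.70,2.311,4.36,4.363,7.25,0.479,1.50,0.289,519.06,182.411
0,0,100,0,3,4,39.88,3.684,9.05,5.546,8.00,0.707,1.00,0.000,1954.42,506.636
0,0,100,0,6,4,101.32,35.475,177.03,26.461,8.00,1.080,3.00,0.577,2593.13,526.681
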