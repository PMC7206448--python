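test_id,dali,hasuike,tokyo,ximing,true_population
1,1.788,2.376,1.742,1.826,hasuike
2,2.499,1.735,2.409,2.419,dali
3,2.439,1.830,2.575,2.375,tokyo
4,2.450,1.693,2.247,2.597,ximing
5,1.696,2.384,1.672,1.651,hasuike
6,1.784,2.156,1.819,1.762,hasuike
7,2.415,1.757,2.287,2.423,ximing
8,2.476,1.595,2.406,2.373,dali
9,1.844,2.509,1.887,1.810,hasuike
10,2.506,1.781,2.373,2.436,dali
11,2.500,1.814,2.280,2.514,ximing
12,2.528,1.714,2.424,2.419,dali
13,2.437,1.735,2.301,2.529,ximing
14,1.843,2.269,1.800,1.828,hasuike
15,2.385,1.856,2.565,2.377,tokyo
16,2.302,1.641,2.461,2.236,tokyo
17,2.365,1.800,2.510,2.266,tokyo
18,2.452,1.725,2.293,2.543,ximing
19,2.491,1.826,2.339,2.561,ximing
20,1.795,2.424,1.762,1.799,hasuike
21,2.471,1.769,2.284,2.467,dali
22,2.379,1.735,2.404,2.290,tokyo
23,2.524,1.779,2.414,2.449,dali
24,2.461,1.771,2.617,2.427,tokyo
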