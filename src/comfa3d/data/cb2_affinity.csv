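receptor,molecule_id,ki_nM,pki,predicted_pki,residual,split
CB2,1,110,6.959,6.974,-0.02,train
CB2,2,98,7.009,7.028,-0.02,train
CB2,3,67,7.174,7.169,0.01,train
CB2,4,50,7.301,7.33,-0.03,train
CB2,5,10.3,7.987,7.964,0.02,train
CB2,7,6.4,8.196,8.174,0.02,train
CB2,10,3.2,8.495,8.536,-0.04,train
CB2,11,3.3,8.481,8.478,0.00,train
CB2,12,4.6,8.337,8.348,-0.01,train
CB2,15,4.4,8.357,8.385,-0.03,train
CB2,17,26,7.585,7.522,0.06,train
CB2,20,11,7.959,7.972,-0.01,train
CB2,21,16,7.796,7.811,-0.02,train
CB2,23,2.6,8.585,8.579,0.01,train
CB2,24,2.1,8.678,8.647,0.03,train
CB2,25,5.9,8.229,8.234,-0.01,train
CB2,27,2.8,8.553,8.545,0.01,train
CB2,28,3.3,8.481,8.5,-0.02,train
CB2,30,1.8,8.745,8.73,0.02,train
CB2,34,8.2,8.086,8.079,0.01,train
CB2,35,2.8,8.553,8.542,0.01,train
CB2,37,17.8,7.75,7.743,0.01,train
CB2,41,0.9,9.056,9.06,0.00,train
CB2,43,2.9,8.538,8.521,0.02,train
CB2,45,1.4,8.854,8.847,0.01,train
CB2,49,31,7.509,7.489,0.02,train
CB2,50,50,7.301,7.299,0.00,train
CB2,51,189,6.724,6.719,0.01,train
CB2,52,12.7,7.896,7.907,-0.01,train
CB2,53,25.4,7.595,7.567,0.03,train
CB2,54,11.2,7.951,7.98,-0.03,train
CB2,55,22.2,7.654,7.651,0.00,train
CB2,56,11.6,7.936,7.964,-0.03,train
CB2,57,2.5,8.606,8.608,0.00,train
CB2,58,2,8.693,8.691,0.00,train
CB2,59,70.8,7.15,7.134,0.02,train
CB2,60,5,8.301,8.299,0.00,train
CB2,61,1.6,8.796,8.806,-0.01,train
CB2,62,3,8.523,8.498,0.03,train
CB2,63,2.5,8.602,8.635,-0.03,train
CB2,64,3.5,8.456,8.452,0.00,train
CB2,65,8.5,8.071,8.082,-0.01,train
CB2,66,0.5,9.292,9.273,0.02,train
CB2,67,9.3,8.032,8.028,0.00,train
CB2,68,3.1,8.509,8.504,0.01,train
CB2,69,9.3,8.032,8.039,-0.01,train
CB2,70,27,7.569,7.556,0.01,train
CB2,71,32,7.495,7.502,-0.01,train
CB2,72,1.9,8.721,8.743,-0.02,train
CB2,73,5.8,8.237,8.254,-0.02,train
CB2,74,9.2,8.036,8.01,0.03,train
CB2,75,2,8.699,8.671,0.03,train
CB2,76,2.1,8.678,8.661,0.02,train
CB2,77,2.2,8.658,8.644,0.01,train
CB2,78,3.1,8.509,8.532,-0.02,train
CB2,79,2.9,8.538,8.554,-0.02,train
CB2,80,20,7.699,7.721,-0.02,train
CB2,81,8.3,8.081,8.066,0.02,train
CB2,82,1.3,8.886,8.884,0.00,train
CB2,83,35,7.456,7.455,0.00,train
CB2,6,5.7,8.242,8.202,0.04,test
CB2,8,3,8.523,8.553,-0.03,test
CB2,9,3.9,8.409,8.651,-0.24,test
CB2,18,58,7.237,7.164,0.07,test
CB2,26,2.3,8.638,8.205,0.43,test
CB2,32,1.3,8.886,8.494,0.39,test
CB2,33,1,9.004,8.606,0.40,test
CB2,36,11.5,7.939,8.209,-0.27,test
CB2,39,0.7,9.187,8.635,0.55,test
CB2,42,1,9,8.53,0.47,test
CB2,48,3.7,8.432,8.264,0.17,test
CB2,84,11.8,7.928,7.283,0.65,test
CB2,85,20.5,7.688,7.353,0.34,test
CB2,86,70,7.155,7.346,-0.19,test
CB2,87,6.6,8.18,8.353,-0.17,test
CB2,88,190,6.721,7.35,-0.63,test
CB2,89,3.8,8.42,8.662,-0.24,test
CB2,90,0.4,9.398,8.863,0.53,test
CB2,91,1.8,8.745,8.715,0.03,test
CB2,92,1.8,8.745,8.557,0.19,test
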