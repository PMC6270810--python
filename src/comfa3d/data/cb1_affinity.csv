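receptor,molecule_id,ki_nM,pki,predicted_pki,residual,split
CB1,1,1660,5.78,5.664,0.12,train
CB1,2,488,6.312,6.223,0.09,train
CB1,3,698,6.156,6.325,-0.17,train
CB1,4,530,6.276,6.352,-0.08,train
CB1,5,3617,5.442,5.462,-0.02,train
CB1,6,2791,5.554,5.526,0.03,train
CB1,7,3621,5.441,5.531,-0.09,train
CB1,8,1258.9,5.9,5.918,-0.02,train
CB1,9,389,6.41,6.353,0.06,train
CB1,10,245.5,6.61,7.022,-0.41,train
CB1,11,1096.5,5.96,5.958,0.00,train
CB1,12,281.8,6.55,6.216,0.33,train
CB1,13,2818.4,5.55,5.665,-0.12,train
CB1,14,776.2,6.11,5.978,0.13,train
CB1,15,851.1,6.07,6.065,0.01,train
CB1,16,1288.2,5.89,5.911,-0.02,train
CB1,17,1698.2,5.77,5.775,-0.01,train
CB1,18,1862.1,5.73,5.808,-0.08,train
CB1,19,229.1,6.64,6.417,0.22,train
CB1,20,363.1,6.44,6.551,-0.11,train
CB1,21,616.6,6.21,6.07,0.14,train
CB1,22,131.8,6.88,6.907,-0.03,train
CB1,23,61.7,7.21,7.036,0.17,train
CB1,24,72.4,7.14,6.948,0.19,train
CB1,25,537,6.27,6.176,0.09,train
CB1,26,562.3,6.25,6.13,0.12,train
CB1,27,91.2,7.04,6.859,0.18,train
CB1,28,213.8,6.67,6.695,-0.03,train
CB1,29,281.8,6.55,6.921,-0.37,train
CB1,30,144.5,6.84,6.605,0.24,train
CB1,31,676.1,6.17,6.083,0.09,train
CB1,32,660.7,6.18,6.222,-0.04,train
CB1,33,380.2,6.42,6.723,-0.30,train
CB1,34,213.8,6.67,6.635,0.04,train
CB1,35,691.8,6.16,6.487,-0.33,train
CB1,36,1258.9,5.9,6.12,-0.22,train
CB1,37,1828.1,5.738,6.141,-0.4,test
CB1,38,12.3,7.91,6.999,0.91,test
CB1,39,13.2,7.88,6.93,0.95,test
CB1,40,44.7,7.35,6.886,0.46,test
CB1,41,33.1,7.48,6.73,0.75,test
CB1,42,28.2,7.55,6.762,0.79,test
CB1,43,1000,6,6.462,-0.46,test
CB1,44,31.6,7.5,6.773,0.73,test
CB1,45,25.1,7.6,6.825,0.77,test
CB1,46,1621.8,5.79,6.218,-0.43,test
CB1,47,354.8,6.45,6.927,-0.48,test
CB1,48,47.9,7.32,6.883,0.44,test
CB1,49,2238.7,5.65,6.124,-0.47,test
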