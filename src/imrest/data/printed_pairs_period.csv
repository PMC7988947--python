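sex,site,observed,expected,relative_deviation,mape,best_scenario
male,colon,1963,1888,-3.8,8.63,C3
male,rectum,1084,985,-9.1,16.83,C3
male,lung,3391,3339,-1.5,4.46,C3
male,prostate,4424,4936,11.6,27.37,L
male,bladder,2635,2594,-1.6,8.48,C1
male,stomach,801,760,-5.1,14.09,C5
male,others,8899,8624,-3.1,3.53,C3
male,all sites (except non-melanoma skin),23197,23126,-0.3,6.34,
female,colon,1467,1413,-3.7,9.99,C5
female,rectum,669,615,-8.1,19.24,C3
female,lung,557,487,-12.6,18.26,L
female,breast,4220,4082,-3.3,14.76,C3
female,corpus uteri,1134,1262,11.3,17.35,C5
female,ovary,615,703,14.3,18.89,L
female,others,7989,8012,0.3,8.68,L
female,all sites (except non-melanoma skin),16651,16574,-0.5,3.85,
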