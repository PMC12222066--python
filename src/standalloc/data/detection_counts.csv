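plot,age_group,window,observed,detected,correct,errors,missed,r,p,f
Y1,middle-aged,0.2x0.2,187,177,158,19,29,0.845,0.893,0.868
Y2,middle-aged,0.1x0.1,250,189,178,11,72,0.712,0.942,0.811
Y3,mature,0.2x0.3,152,120,112,8,40,0.737,0.933,0.824
Y4,overripe,0.3x0.3,113,116,108,8,5,0.956,0.931,0.943
Y5,overripe,0.3x0.3,92,100,87,13,5,0.946,0.870,0.906
Y6,near-ripe,0.2x0.2,160,153,142,11,18,0.888,0.928,0.907
Y7,overripe,0.3x0.2,112,126,98,28,14,0.875,0.778,0.824
Y8,near-ripe,0.3x0.2,157,139,125,14,32,0.796,0.899,0.845
Y9,near-ripe,0.2x0.1,149,155,129,26,20,0.866,0.832,0.849
Y10,middle-aged,0.4x0.4,83,70,69,1,14,0.831,0.986,0.902
Y11,middle-aged,0.4x0.4,91,89,83,6,8,0.912,0.933,0.922
Y12,middle-aged,0.3x0.4,74,71,59,12,15,0.797,0.831,0.814
Y13,overripe,0.4x0.4,50,53,44,9,6,0.880,0.830,0.854
Y14,overripe,0.4x0.5,44,48,40,8,4,0.909,0.833,0.870
Y15,mature,0.5x0.6,40,41,34,7,6,0.850,0.829,0.840
Y16,overripe,0.3x0.2,102,108,85,23,17,0.833,0.787,0.810
Y17,overripe,0.2x0.3,114,116,101,15,13,0.886,0.871,0.878
Y18,overripe,0.1x0.2,125,116,99,17,26,0.792,0.853,0.822
Y19,overripe,0.1x0.2,118,115,103,12,15,0.873,0.896,0.884
Y20,mature,0.1x0.2,139,122,112,10,27,0.806,0.918,0.858
Y21,near-ripe,0.2x0.2,135,106,99,7,36,0.733,0.934,0.822
Y22,near-ripe,0.2x0.2,152,121,111,10,41,0.730,0.917,0.813
Y23,middle-aged,0.2x0.2,156,133,119,14,37,0.763,0.895,0.824
Y24,near-ripe,0.2x0.3,118,108,97,11,21,0.822,0.898,0.858
Y25,mature,0.5x0.5,62,71,56,15,6,0.903,0.789,0.842
Y26,mature,0.5x0.3,88,90,72,18,16,0.818,0.800,0.809
Y27,mature,0.2x0.5,75,77,64,13,11,0.853,0.831,0.842
Y28,overripe,0.5x0.4,47,42,39,3,8,0.830,0.929,0.876
Y29,overripe,0.4x0.4,79,71,62,9,17,0.785,0.873,0.827
Y30,overripe,0.5x0.5,40,43,38,5,2,0.950,0.884,0.916
Y31,young,0.2x0.5,152,132,130,2,22,0.855,0.985,0.915
Y32,young,0.1x0.4,162,152,143,9,19,0.883,0.941,0.911
Y33,young,0.1x0.2,193,170,155,15,38,0.803,0.912,0.854
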