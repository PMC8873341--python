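subject,10,20,30,40,50,60
Subject 1,49.54,58.51,65.33,74.61,89.16,95.36
Subject 2,45.20,59.75,73.37,80.80,86.38,91.95
Subject 3,44.58,53.87,67.80,69.66,84.52,91.64
Subject 4,63.78,64.09,65.02,90.71,93.19,95.67
Subject 5,52.94,73.68,83.59,94.74,96.90,96.59
Subject 6,59.75,68.73,77.71,84.52,95.05,93.19
Subject 7,52.01,71.52,77.40,85.14,88.24,95.05
Subject 8,39.32,61.61,74.61,84.21,88.24,96.59
Subject 9,59.75,63.16,74.61,77.40,89.47,91.33
Subject 10,47.37,62.23,78.33,85.76,93.19,97.83
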