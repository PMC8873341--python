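subject,10,20,30,40,50,60
Subject 1,42.11,66.25,63.78,59.44,68.73,71.83
Subject 2,55.11,67.18,69.35,70.59,76.16,74.61
Subject 3,58.20,60.37,60.99,64.09,63.78,60.68
Subject 4,53.87,64.40,67.49,72.14,72.45,67.49
Subject 5,48.61,66.25,64.09,64.40,69.04,66.87
Subject 6,48.61,65.02,67.80,64.71,73.68,68.42
Subject 7,53.56,62.54,59.75,67.80,67.18,66.56
Subject 8,52.32,59.75,65.02,67.80,68.11,70.59
Subject 9,53.25,67.18,65.63,66.87,59.44,72.45
Subject 10,55.73,60.68,65.02,63.47,59.75,69.97
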