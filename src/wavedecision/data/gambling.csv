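study_id,p_again_win,p_again_lose,p_win,p_lose,p_again_unknown,theta_expt,theta1,theta2,theta3,theta4,theta_fit,p_fit
G1,0.69,0.57,0.5,0.5,0.38,113.49,134.37,146.22,138.83,139.59,106.89,0.45
G2,0.69,0.59,0.5,0.5,0.35,117.03,134.64,146.19,138.32,140.53,106.91,0.40
G3,0.71,0.56,0.5,0.5,0.84,71.03,133.80,147.43,139.35,139.02,106.29,0.46
G4,0.60,0.47,0.5,0.5,0.47,97.03,135.28,142.49,140.66,136.54,108.75,0.36
G5,0.83,0.70,0.5,0.5,0.62,100.97,133.41,161.46,137.71,148.57,99.27,0.64
G6,0.80,0.37,0.5,0.5,0.43,106.55,129.29,153.45,146.31,131.19,103.27,0.46
G7,0.68,0.32,0.5,0.5,0.38,104.91,131.30,147.14,147.14,131.30,106.43,0.37
G8,0.64,0.47,0.5,0.5,0.38,108.61,134.24,144.18,141.11,136.12,107.91,0.39
G9,0.30,0.24,0.5,0.5,0.17,111.88,147.53,136.74,152.19,134.71,111.63,0.17
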