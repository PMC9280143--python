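study_id,face_type,p_attack_good,p_attack_bad,p_good,p_bad,p_attack_alone,theta_expt,theta1,theta2,theta3,theta4,theta_fit,p_fit
CD1-W,W,0.35,0.52,0.84,0.16,0.39,87.65,129.33,145.09,180.00,157.52,85.58,0.40
CD1-N,N,0.41,0.63,0.17,0.83,0.69,75.22,155.02,180.00,143.12,129.90,75.08,0.69
CD2-W,W,0.37,0.53,0.80,0.20,0.39,91.94,130.26,143.02,180.00,151.00,86.72,0.42
CD2-N,N,0.45,0.64,0.20,0.80,0.69,78.17,149.86,180.00,143.74,129.88,80.25,0.67
CD3-W,W,0.39,0.52,0.78,0.22,0.42,89.79,131.11,141.50,166.60,149.73,87.39,0.44
CD3-N,N,0.41,0.58,0.21,0.79,0.59,83.39,151.13,171.19,139.60,131.91,76.96,0.63
CD4-W,W,0.33,0.53,0.78,0.22,0.37,90.66,129.21,146.10,180.00,146.32,84.69,0.41
CD4-N,N,0.37,0.61,0.24,0.76,0.60,83.26,144.91,165.06,141.37,130.92,84.17,0.59
CD5-W,W,0.34,0.58,0.77,0.23,0.39,90.80,129.42,144.97,171.74,144.65,85.62,0.42
CD5-N,N,0.33,0.66,0.24,0.76,0.62,84.36,141.78,173.30,144.65,129.17,89.05,0.59
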