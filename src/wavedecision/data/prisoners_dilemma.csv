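study_id,p_defect_kd,p_defect_kc,p_kd,p_kc,p_defect_unknown,theta_expt,theta1,theta2,theta3,theta4,theta_fit,p_fit
PD1,0.73,0.67,0.5,0.5,0.60,98.23,134.78,149.39,137.09,144.87,105.30,0.52
PD2,0.80,0.77,0.5,0.5,0.63,101.29,134.89,159.52,135.97,155.71,100.24,0.64
PD3,0.90,0.87,0.5,0.5,0.87,91.08,134.60,180.00,135.62,180.00,90.00,0.88
PD4,0.83,0.80,0.5,0.5,0.70,98.21,134.77,172.23,135.83,164.44,93.88,0.76
PD5,0.83,0.73,0.5,0.5,0.70,96.12,133.82,164.17,137.08,152.39,97.92,0.68
PD6,0.77,0.83,0.5,0.5,0.80,90.00,136.44,157.27,134.29,167.16,101.36,0.64
PD7,0.87,0.73,0.5,0.5,0.77,92.39,133.25,180.00,137.55,153.63,90.00,0.80
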