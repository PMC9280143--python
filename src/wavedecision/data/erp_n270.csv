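electrode,amplitude_pos,amplitude_neg,amplitude_neutral,theta_printed
F7,7.93,4.6,5.19,141.26
F8,8.42,5.13,6.45,129.79
T5,5.66,2.69,3.61,149.32
T6,5.18,2.24,3.36,152.87
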