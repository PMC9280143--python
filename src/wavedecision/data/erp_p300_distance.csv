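electrode,amplitude_pos,amplitude_neg,amplitude_neutral,theta_printed
Fz,20.93,14.94,16.29,129.05
FCz,22.91,16.95,18.29,128.32
Cz,23.88,18.83,20.23,124.75
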