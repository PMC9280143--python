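electrode,amplitude_pos,amplitude_neg,amplitude_neutral,theta_printed
CentralZero,8.86,12.11,10.31,123.37
RightPart,9.95,12.38,10.36,126.16
CentralZone,8.35,10.91,9.41,123.36
ParietalZone,11.72,15.49,12.54,127.59
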