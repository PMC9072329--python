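device_output,ASD_positive,ASD_negative_other_condition,ASD_negative_neurotypical
positive,63,15,0
indeterminate,58,206,26
negative,1,42,14
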