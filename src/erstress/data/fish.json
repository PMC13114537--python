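{"change_times": [110, 130, 150, 170]}
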