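time
91.00
93.00
94.00
98.20
115.81
116.00
116.50
117.25
126.75
127.50
154.33
159.50
164.00
184.14
188.33
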