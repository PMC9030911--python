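level,social,fear,control
D1,51,48,42
D2,55,61,62
D3,24,22,26
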