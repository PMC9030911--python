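level,social,fear,control
never,9,3,7
sometimes,21,36,33
usually,30,33,32
always,70,59,58
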