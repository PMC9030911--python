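level,social,fear,control
never,15,18,20
sometimes,41,42,36
usually,65,64,70
always,9,6,4
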