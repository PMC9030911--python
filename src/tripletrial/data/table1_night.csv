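level,social,fear,control
never,34,42,36
sometimes,41,43,45
usually,32,26,33
always,22,19,16
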