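level,social,fear,control
yes,83,85,84
no,44,41,44
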