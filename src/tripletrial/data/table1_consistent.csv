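level,social,fear,control
yes,69,69,69
no,61,62,61
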