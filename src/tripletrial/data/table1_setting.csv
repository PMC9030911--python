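level,social,fear,control
urban,25,29,30
suburban,24,32,23
both,78,69,70
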