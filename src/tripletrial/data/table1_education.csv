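level,social,fear,control
elementary_or_none,86,85,90
junior_high_or_above,41,38,35
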