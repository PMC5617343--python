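glad
happy
relieved
grateful
excited
thrilled
thankful
great
lucky
pleased
blessed
fortunate
hopeful
inspiring
encouraging
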