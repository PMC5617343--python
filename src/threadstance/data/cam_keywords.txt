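alternative
cam
ginseng
marijuana
supplement
cream
massage
tcm
gerson
laetrile
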