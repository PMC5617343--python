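scared
sad
anxious
embarrassing
disappointing
confused
heartbreaking
frightened
frustrated
angry
upset
distress
stress
discouraging
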