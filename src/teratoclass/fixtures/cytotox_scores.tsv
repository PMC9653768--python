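system	score
UKN1	4318
UKK2	4257
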