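procedure	system	bucket	threshold
sps	UKN1	1x	1
sps	UKN1	20x	1000
sps	UKK2	1x	270
sps	UKK2	20x	360
sps	mean	1x	130
sps	mean	20x	500
top1000	UKN1	1x	0.2
top1000	UKN1	20x	0.4
top1000	UKK2	1x	0.25
top1000	UKK2	20x	0.15
top1000	mean	1x	0.36
top1000	mean	20x	0.29
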