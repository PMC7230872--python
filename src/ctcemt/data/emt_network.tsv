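source	target	sign
SNAIL	ZEB	1
SNAIL	miR200	-1
miR200	ZEB	-1
ZEB	miR200	-1
GRHL2	ZEB	-1
ZEB	GRHL2	-1
ZEB	CDH1	-1
SNAIL	CDH1	-1
GRHL2	CDH1	1
ZEB	VIM	1
GRHL2	VIM	-1
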