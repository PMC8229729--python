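# target genes driving the planted response
TG0001
TG0002
TG0003
TG0004
TG0005
TG0006
TG0007
TG0008
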