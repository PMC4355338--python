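isoform	total
I	14
II	26
III	8
IV	4
V	11
VI	7
VII	11
IX	23
XII	9
XIII	15
XIV	16
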