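position	I	II	III	IV	V	VI	VII	IX	XII	XIII	XIV
I91	F	I	R	K	K	Q	K	L	T	R	A
V121	A	V	V	V	V	V	V	V	V	V	V
V135	A	V	L	Q	S	Q	A	L	S	A	A
V141	L	L	L	I	L	L	L	L	L	L	L
V143	V	V	V	V	V	V	V	V	V	V	V
L198	L	L	F	L	L	L	L	L	L	L	L
P202	P	P	T	P	P	P	P	P	P	P	P
L204	Y	L	E	D	A	T	S	A	N	L	Y
W209	W	W	W	W	W	W	W	W	W	W	W
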