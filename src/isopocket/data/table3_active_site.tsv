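position	II	I	III	IV	VA	VB	VI	VII	IX	XII	XIII	XIV
Y7	Y	Y	Y	Y	W	Y	Y	Y	Y	Y	Y	Y
N62	N	N	N	N	N	N	N	N	N	N	N	N
N67	N	H	R	M	Q	L	Q	Q	Q	K	N	Q
I91	I	F	R	K	K	K	Q	K	L	T	R	A
Q92	Q	Q	Q	Q	Q	Q	Q	Q	Q	Q	Q	Q
H94	H	H	H	H	H	H	H	H	H	H	H	H
H96	H	H	H	H	H	H	H	H	H	H	H	H
H119	H	H	H	H	H	H	H	H	H	H	H	H
V121	V	A	V	V	V	V	V	V	V	V	V	V
F131	F	L	F	V	Y	F	Y	F	V	A	F	L
V135	V	A	L	Q	V	A	Q	A	L	S	A	A
V143	V	V	V	V	V	V	V	V	V	V	V	V
L198	L	L	F	L	L	L	L	L	L	L	L	L
T199	T	T	T	T	T	T	T	T	T	T	T	T
T200	T	T	T	T	T	T	T	T	T	T	V	T
P202	P	P	T	P	P	P	P	P	P	P	P	P
W209	W	W	W	W	W	W	W	W	W	W	W	W
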