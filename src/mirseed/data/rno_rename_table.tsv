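previous_name	updated_name	family_id
rno-mir-16	rno-mir-16-2	MIPF0000006
rno-mir-365	rno-mir-365-2	MIPF0000061
rno-mir-883	rno-mir-883a	MIPF0000389
rno-mir-17-1	rno-mir-17	MIPF0000001
rno-mir-17-2	rno-mir-106a	MIPF0000001
rno-mir-135a	rno-mir-135a-2	MIPF0000028
rno-mir-199a	rno-mir-199a-2	MIPF0000040
rno-mir-26a	rno-mir-26a-1	MIPF0000043
rno-mir-486	rno-mir-486b	MIPF0000220
rno-mir-3074	rno-mir-3074-1	MIPF0001103
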