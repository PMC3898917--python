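position	araguaiaensis	geoffrensis	boliviensis
38	C	T	T
45	T	T	C
51	A	A	T
120	C	T	C
138	A	A	G
165	T	C	C
177	C	T	T
186	T	C	C
198	C	T	C
201	T	T	C
210	T	C	C
244	T	T	C
258	G	A	G
264	T	C	C
282	C	T	T
291	T	C	T
306	G	G	A
361	C	T	T
365	T	T	C
375	T	C	T
384	C	T	T
480	G	A	A
555	T	C	C
574	C	T	C
576	A	A	G
582	C	T	T
585	A	G	C
589	C	C	T
633	T	C	C
654	C	C	T
657	A	A	T
690	A	A	G
693	G	A	A
699	C	T	T
702	A	A	G
724	T	T	C
745	T	C	C
753	G	A	A
770	T	C	C
771	C	C	T
792	C	C	T
801	T	C	C
807	G	G	A
813	G	G	A
816	A	G	G
819	T	C	T
825	G	G	A
850	G	A	A
867	A	G	G
870	G	A	A
873	A	G/C	A
891	A	A	G
909	C	T	C
924	T	C	T
984	A	T	A/G
1008	A	C	A
1020	T	C	C
1041	T	C	C
1047	C	C	T
1048	A	G	A
1066	C	A	A
1080	T	C	T
1089	A	G	A
1092	A	G	G
1113	T	C	T
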