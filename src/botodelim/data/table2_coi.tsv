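position	araguaiaensis	geoffrensis	boliviensis
24	A	A	G
30	C	C	T
51	G	A	G
60	T	C	T
87	G	A	A
99	T	C	T
125	G	A	G
159	T	T	C
174	A	G	G
177	T	C	T
180	A	A	G
231	A	G	A
241	A	G	G
243	A	G	G
258	A	G	G
270	A	G	A
276	T	T	C
279	G	A	G
288	T	T	C
291	G	G	A
309	C	C	T
327	C	T	C
353	C	T	C
374	G	A	A
381	A	G	A
387	A	G	G
395	G	A	A
417	G	A	G
426	G	G	A
435	A	A	G
498	T	T	C
507	A	A	G
519	G	A	G
531	C	T	C
552	A	A	G
558	T	C	C
582	A	T	A
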