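K	repetitions	mean_lnP	stdev_lnP
1	20	-3124.565000	0.198083
2	20	-2264.810000	0.656867
3	20	-2041.115000	1.433169
4	20	-2041.505000	15.357408
5	20	-2104.215000	36.519573
6	20	-2172.155000	71.411944
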