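rank	stratum	weight
1	All living organisms	0.20
2	Eukaryota	0.07
3	Opisthokonta	0.03
4	Holozoa	0.03
5	Metazoa	0.06
6	Eumetazoa	0.04
7	Bilateria	0.05
8	Deuterostomia	0.03
9	Chordata	0.04
10	Olfactores	0.03
11	Craniata	0.03
12	Euteleostomi	0.14
13	Tetrapoda	0.03
14	Amniota	0.03
15	Mammalia	0.05
16	Boreoeutheria	0.03
17	Eutheria	0.04
18	Euarchontoglires	0.03
19	Primates	0.04
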