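All living organisms
Eukaryota
Opisthokonta
Holozoa
Metazoa
Eumetazoa
Bilateria
Deuterostomia
Chordata
Olfactores
Craniata
Euteleostomi
Tetrapoda
Amniota
Mammalia
Boreoeutheria
Eutheria
Euarchontoglires
Primates
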