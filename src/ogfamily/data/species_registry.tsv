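# Eight-species angiosperm panel: basal outgroup + three monocots + four dicots.
code	name	lineage	order	family
Amb	Amborella trichopoda	basal	Amborellales	Amborellaceae
Ma	Musa acuminata	monocot	Zingiberales	Musaceae
Pd	Phoenix dactylifera	monocot	Arecales	Arecaceae
Os	Oryza sativa	monocot	Poales	Poaceae
Vv	Vitis vinifera	dicot	Vitales	Vitaceae
Tc	Theobroma cacao	dicot	Malvales	Malvaceae
At	Arabidopsis thaliana	dicot	Brassicales	Brassicaceae
Cc	Coffea canephora	dicot	Gentianales	Rubiaceae
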