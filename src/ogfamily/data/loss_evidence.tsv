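# Wider-taxon presence/absence evidence for orthogroups with lineage losses,
# from searches of public protein databases beyond the eight sampled species.
# Presence in an unsampled sister lineage (e.g. Cleomaceae for OG-PAT-2) is
# recorded at the nearest named ancestor clade of the taxonomy.
og	clade	status
OG-SCR-3	Brassicales	absent
OG-SHR-2	Poales	absent
OG-SHR-2	Brassicales	absent
OG-SCL32-2	Brassicales	absent
OG-NSP2-2	Malvales	absent
OG-NSP2-2	Brassicales	absent
OG-NSP2-3	monocots	absent
OG-HAM-I	Poales	absent
OG-DELLA-2	Brassicales	absent
OG-PAT-2	Brassicales	present
OG-RAD1-1	Brassicales	absent
OG-RAD1-2	Poales	absent
OG-RAD1-2	Brassicales	absent
OG-RAM1	Brassicales	absent
OG-SCLA	Brassicales	absent
OG-SCLB	Poales	absent
OG-SCLB	Brassicales	absent
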