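# Three-group residue partitions for the CTD (composition/transition/
# distribution) descriptors: 7 physicochemical attributes, each splitting
# the 20 standard residues into 3 disjoint, exhaustive groups.  version: 1
attribute	group1	group2	group3
hydrophobicity	RKEDQN	GASTPHY	CLVIMFW
vdw_volume	GASTCPD	NVEQIL	MHKFRYW
polarity	LIFWCMVY	PATGS	HQRKNED
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
secondary_structure	EALMQKRH	VIYCWFT	GNPSD
solvent_accessibility	ALFCGIVW	RKQEND	MPSTHY
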