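# Thirteen physicochemical grouping scales for CTD descriptors: the seven
# core scales plus six further hydrophobicity scales, each named after its
# AAindex accession (Tomii & Kanehisa 1996 clusters; the partitions used by
# standard CTD implementations). 13 scales x 3 groups = 39 composition
# features. Every row is validated at load time to be a disjoint cover of
# the 20-letter amino-acid alphabet.
#
# For the hydrophobicity scales: 1=polar, 2=neutral, 3=hydrophobic.
#
# property	group1	group2	group3
secondarystruct	EALMQKRH	VIYCWFT	GNPSD
hydrophobicity_PRAM900101	RKEDQN	GASTPHY	CLVIMFW
normwaalsvolume	GASTPDC	NVEQIL	MHKFRYW
solventaccess	ALFCGIVW	RKQEND	MSPTHY
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
polarity	LIFWCMVY	PATGS	HQRKNED
hydrophobicity_ARGP820101	QSTNGDE	RAHCKMV	LYPFIW
hydrophobicity_ZIMJ680101	QNGSWTDERA	HMCKV	LPFYI
hydrophobicity_PONP930101	KPDESNQT	GRHA	YMFWLCVI
hydrophobicity_CASG920101	KDEQPSRNTG	AHYMLV	FIWC
hydrophobicity_ENGD860101	RDKENQHYP	SGTAW	CVLIMF
hydrophobicity_FASG890101	KERSQD	NTPG	AYHWVMFLIC
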