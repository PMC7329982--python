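# Seven physicochemical grouping scales for CTD descriptors.
# Each scale partitions the 20 canonical amino acids into three groups,
# following the Tomii & Kanehisa (1996) amino-acid-index clusters as used
# by standard CTD implementations (AAindex-derived). Published transcriptions
# of these tables occasionally contain typos (duplicated or missing residues);
# the rows below are the canonical partitions and every row is validated at
# load time to be a disjoint cover of ACDEFGHIKLMNPQRSTVWY.
#
# Group semantics:
#   secondarystruct:            1=helix     2=strand    3=coil
#   hydrophobicity_PRAM900101:  1=polar     2=neutral   3=hydrophobic
#   normwaalsvolume:            1=0-2.78    2=2.95-4.0  3=4.03-8.08
#   solventaccess:              1=buried    2=exposed   3=intermediate
#   polarizability:             1=0-0.108   2=0.128-0.186  3=0.219-0.409
#   charge:                     1=positive  2=neutral   3=negative
#   polarity:                   1=4.9-6.2   2=8.0-9.2   3=10.4-13.0
#
# property	group1	group2	group3
secondarystruct	EALMQKRH	VIYCWFT	GNPSD
hydrophobicity_PRAM900101	RKEDQN	GASTPHY	CLVIMFW
normwaalsvolume	GASTPDC	NVEQIL	MHKFRYW
solventaccess	ALFCGIVW	RKQEND	MSPTHY
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
polarity	LIFWCMVY	PATGS	HQRKNED
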