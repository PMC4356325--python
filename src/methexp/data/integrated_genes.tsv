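gene	accession	name	group	category	delta	fold_change	ccdb	gent
SYT11	NM_152280.2	Synaptotagmin XI	cancer	down_by_hyper	0.32	-2.70	absent	down
CAMK2N1	NM_018584.4	Calcium/calmodulin-dependent protein kinase II inhibitor 1	cancer	down_by_hyper	0.28	-4.95	absent	up
ALDH1A3	NM_000693.1	Aldehyde dehydrogenase 1 family, member A3	cancer	down_by_hyper	0.27	-3.08	absent	not_changed
PRRX1	NM_006902.3	Paired related homeobox 1, transcript variant pmx-1a	cancer	down_by_hyper	0.25	-3.18	absent	down
PPP1R3C	NM_005398.3	Protein phosphatase 1, regulatory (inhibitor) subunit 3C	cancer	down_by_hyper	0.22	-6.18	down	down_highly
MAP1LC3A	NM_181509.1	Microtubule-associated protein 1 light chain 3 alpha, transcript variant 2	cancer	down_by_hyper	0.22	-3.14	absent	down
PHF21B	NM_138415.1	PHD finger protein 21B	cancer	down_by_hyper	0.20	-2.06	absent	down_highly
TPM1	NM_001018004.1	Tropomyosin 1 (alpha), transcript variant 7	cancer	down_by_hyper	0.20	-2.07	absent	down_highly
PPP1R14A	NM_033256.1	Protein phosphatase 1, regulatory (inhibitor) subunit 14A	cancer	down_by_hyper	0.20	-2.91	absent	down_highly
PLOD2	NM_000935.2	Procollagen-lysine, 2-oxoglutarate 5-dioxygenase 2, transcript variant 2	cancer	up_by_hypo	-0.25	2.66	up	up_highly
FAT1	NM_005245.3	FAT tumor suppressor homolog 1 (Drosophila)	cancer	up_by_hypo	-0.23	3.44	absent	absent
EXT1	NM_000127.2	Exostoses (multiple) 1	cancer	up_by_hypo	-0.22	2.40	absent	up
TMEM44	NM_138399.3	Transmembrane protein 44, transcript variant 1	cancer	up_by_hypo	-0.21	3.02	absent	up
SNCAIP	NM_005460.2	Synuclein, alpha interacting protein	pre-cancer	down_by_hyper	0.23	-2.39	absent	down
A2M	NM_000014.4	Alpha-2-macroglobulin	pre-cancer	down_by_hyper	0.21	-2.22	up	down
CGNL1	NM_032866.3	Cingulin-like 1	pre-cancer	down_by_hyper	0.21	-3.14	absent	down_highly
DLC1	NM_024767.2	Deleted in liver cancer 1, transcript variant 3	pre-cancer	down_by_hyper	0.20	-2.45	down	down_highly
RNF150	NM_020724.1	Ring finger protein 150	pre-cancer	down_by_hyper	0.20	-2.18	absent	down_highly
MUC4	NM_018406.3	Mucin 4, cell surface-associated, transcript variant 1	pre-cancer	up_by_hypo	-0.21	2.94	absent	up
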