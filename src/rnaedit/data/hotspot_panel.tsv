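# Curated hotspot A-to-I editing site panel (GRCh38 coordinates, 1-based).
# ref_base_plus: plus-strand reference base at the site; A means editing is
# observed as A>G on the plus strand, T means it is observed as T>C.
gene	chrom	pos	ref_base_plus	label
AZIN1	chr8	102829408	T	nonsynonymous (S367G)
BLCAP	chr20	37519131	T	nonsynonymous (K15R)
BLCAP	chr20	37519161	T	nonsynonymous (Q5R)
COG3	chr13	45516236	T	nonsynonymous (I635V)
COPA	chr1	160332454	T	nonsynonymous (I164V)
EEF1A1	chr6	73519351	T	nonsynonymous (T104A)
FLNA	chrX	154351589	T	nonsynonymous (S2339G)
FLNB	chr3	58156074	A	nonsynonymous (Q2296R)
FTH1	chr11	61964742	T	synonymous (S179S)
FTH1	chr11	61965059	T	synonymous (L105L)
GIPC1	chr19	14482881	A	synonymous (P32P)
IGFBP7	chr4	57110068	T	nonsynonymous (K95R)
IGFBP7	chr4	57110120	T	nonsynonymous (R78G)
NEIL1	chr15	75353745	A	nonsynonymous (K242R)
RPL15	chr3	23919466	A	nonsynonymous (R194G)
RPL24	chr3	101685872	A	synonymous (P46P)
RPL32	chr3	12839479	A	nonsynonymous (K50E)
RPL7A	chr9	133350718	A	nonsynonymous (Q206R)
RPL7A	chr9	133351290	T	nonsynonymous (L242P)
RPLP1	chr15	69455463	T	nonsynonymous (S101P)
RPS23	chr5	82277737	T	synonymous (P40P)
RPS9	chr19	54206321	A	nonsynonymous (E89G)
UQCRHL	chr1	15807419	T	synonymous (A77A)
ZNF358	chr19	7520387	A	nonsynonymous (K382R)
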