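gene_id	locus_name	chromosome	protein_length	predicted_localizations	tm_segments
GmaPHO1;H1	Glyma02g00640	2	763	PM,Nuc	7
GmaPHO1;H2	Glyma07g35520	7	801	PM,Nuc	8
GmaPHO1;H3	Glyma09g37000	9	756	PM,Nuc	6
GmaPHO1;H4	Glyma10g00720	10	764	PM,Nuc	5
GmaPHO1;H5	Glyma10g32670	10	771	PM,Nuc	7
GmaPHO1;H6	Glyma18g49680	18	773	PM,Nuc	6
GmaPHO1;H7	Glyma20g03960	20	784	PM,Nuc	5
GmaPHO1;H8	Glyma20g34930	20	771	PM,Nuc	7
GmaPHO1;H9	Glyma20g04130	20	792	PM,Nuc,ER	7
GmaPHO1;H10	Glyma20g04150	20	804	PM,Nuc,ER	9
GmaPHO1;H11	Glyma20g04160	20	817	PM,Nuc	8
GmaPHO1;H12	Glyma01g22990	1	804	PM,Nuc,ER	7
GmaPHO1;H13	Glyma02g12320	2	753	PM,ER	6
GmaPHO1;H14	Glyma02g14440	2	789	PM,Vac	6
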