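gene	chrom	position	type_label	coding_hgvs	protein_hgvs	coverage	gnomad_af	internal_ref_count	insilico_verdict	in_domain	splicing_impact	zygosity	carriers
SMCHD1	18	2688462	missense	c.709G>A	p.Val237Ile	100	—	0	moderate_pathogenic	true	na	het	FSHD9A
SMCHD1	18	2739518	missense in splicing region	c.3514G>T	p.Val1172Phe	100	—	0	strong_pathogenic	false	broken_site	het	FSHD10A
SMCHD1	18	2743927	splicing	c.3801+1dup	—	100	—	0	na	false	na	het	FSHD11A
SMCHD1	18	2700830	missense	c.1561G>T	p.Val521Phe	100	—	0	moderate_pathogenic	true	na	het	FSHD12A
SMCHD1	18	2700798	missense	c.1529C>T	p.Ser510Phe	100	—	0	moderate_pathogenic	true	na	het	FSHD13A
SMCHD1	18	2707627	frameshift	c.2129dup	p.A711Cfs*11	100	—	0	na	false	na	het	FSHD14A
SMCHD1	18	2656258	frameshift	c.182_183dup	p.Q62Vfs*48	100	—	0	na	false	na	het	FSHD15A
SMCHD1	18	2697122	splicing	c.1131+2_1131+5del	—	100	—	0	na	false	na	het	FSHD16A
SMCHD1	18	2747559	missense	c.3841A>G	p.Ile1281Val	100	0.000278	0	supporting_benign	false	na	het	FSHD17A
SMCHD1	18	2743774	missense	c.3649A>G	p.Ile1217Val	100	—	0	supporting_benign	false	na	het	FSHD18A
SMCHD1	18	2747512	splicing	c.3802-8C>A	—	100	0.000004	0	na	false	none	het	FSHD19A
SMCHD1	18	2784527	missense	c.5627T>C	p.Leu1876Pro	100	—	0	uncertain	false	na	het	FSHD1A
LRIF1	1	111494758	frameshift	c.748del	p.Tyr250ThrfsTer8	100	—	0	na	false	na	het	FSHD1A
DNMT3B	20	31383232	missense	c.1144C>T	p.Arg382Cys	100	0.00053	0	uncertain	false	na	het	FSHD8A
CTCF	16	67660583	missense	c.1483T>G	p.Phe495Val	100	not found	0	moderate_pathogenic	true	na	het	FSHD2A
EZH2	7	148525892	inframe insertion	c.566_568dup	p.Asp189dup	100	0.000004	0	moderate_pathogenic	true	new_site	het	FSHD3A
EZH2	7	148525853	missense	c.604G>A	p.Asp202Asn	100	0.000004	0	supporting_benign	true	na	het	FSHD4A
DNMT1	19	10249229	missense	c.4001C>T	p.Ala1334Val	100	0.00005	0	uncertain	true	na	het	FSHD7A
DNMT3A	2	25470585	missense	c.889T>G	p.Trp297Gly	100	0.000014	0	moderate_pathogenic	true	na	het	FSHD5A
SUV39H1	X	48558704	missense	c.421C>T	p.Arg141Cys	100	not found	0	uncertain	false	na	het	FSHD6A
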