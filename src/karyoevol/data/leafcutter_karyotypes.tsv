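group	taxon	haploid_n	diploid_2n	locality	formula	genome_mbp	genome_pg	fn_printed	preferred
leafcutting	Amoimyrmex striatus	11	22	Brazil	20 m + 2sm	342.3	0.35	44	1
leafcutting	Amoimyrmex bruchi	11	22	Argentina	20 m + 2sm	298.8	0.31	44	1
leafcutting	Amoimyrmex silvestrii	11	22	Argentina	20 m + 2sm	311.37	0.32	44	1
leafcutting	Atta bisphaerica	11	22	Brazil	12 m + 6sm + 4st			40	1
leafcutting	Atta colombica	11	22	Panama	12 m + 6sm + 4st	298.8	0.31	40	1
leafcutting	Atta laevigata	11	22	Brazil	12 m + 6sm + 4st	322.74	0.33	40	1
leafcutting	Atta sexdens	11	22	Brazil	12 m + 6sm + 4st	322.74	0.33	40	1
leafcutting	Atta robusta	11	22	Brazil	18 m + 2sm + 2st	332.52	0.34	44	1
leafcutting	Atta sexdens	11	22	French Guiana	18 m + 2sm + 2st	322.74	0.33	44	0
leafcutting	Acromyrmex ambiguus	19	38	Uruguay	2 m + 6sm + 16st + 14 t	322.74	0.33	62	1
leafcutting	Acromyrmex ambiguus	19	38	Brazil	14 m + 12sm + 8st + 4 t			68	0
leafcutting	Acromyrmex crassispinus	19	38	Brazil	2 m + 6sm + 16st + 14 t	332.52	0.34	62	1
leafcutting	Acromyrmex crassispinus	19	38	Brazil	12 m + 20sm + 4st + 2 t	332.52	0.34	74	0
leafcutting	Acromyrmex heyeri	19	38	Uruguay	2 m + 6sm + 16st + 14 t			62	1
leafcutting	Acromyrmex lundi	19	38	Brazil	10 m + 14sm + 10st + 4 t			72	1
leafcutting	Acromyrmex nigrosetosus	19	38	Brazil	12 m + 14sm + 10st + 2 t	342.3	0.35	74	1
leafcutting	Acromyrmex hispidus	19	38	Uruguay	2 m + 6sm + 16st + 14 t			62	1
leafcutting	Acromyrmex molestans	19	38	Brazil	2 m + 6sm + 16st + 14 t	332.52	0.34	62	1
leafcutting	Acromyrmex molestans	19	38	Brazil	10 m + 10sm + 16st + 2 t	332.52	0.34	74	0
leafcutting	Acromyrmex subterraneus	19	38	Brazil	2 m + 6sm + 16st + 14 t	342.3	0.35	62	1
leafcutting	Acromyrmex subterraneus	19	38	Brazil	14 m + 18sm + 4st + 2 t	342.3	0.35	74	0
leafcutting	Acromyrmex balzani	19	38	Brazil, French Guiana	12 m + 10sm + 14st + 2 t	361.86	0.37	74	1
leafcutting	Acromyrmex coronatus	19	38	Brazil	12 m + 8sm + 16st + 2 t	332.52	0.34	74	1
leafcutting	Acromyrmex disciger	19	38	Brazil	10 m + 12sm + 14st + 2 t	322.74	0.33	74	1
leafcutting	Acromyrmex echinatior	19	38	Brazil	8 m + 6sm + 14st + 10 t	335	0.36	66	1
leafcutting	Acromyrmex niger	19	38	Brazil	12 m + 14sm + 10st + 2 t	352.08	0.36	74	1
leafcutting	Acromyrmex rugosus	19	38	Brazil	16 m + 12sm + 8st + 2 t	342.3	0.35	74	1
leafcutting	Acromyrmex aspersus	19	38	Brazil	8 m + 10sm + 16st + 4 t			72	1
leafcutting	Acromyrmex ameliae	18	36	Brazil	2 m + 8sm + 20st + 6 t			66	1
leafcutting	Acromyrmex brunneus	19	38	Brazil	2 m + 6sm + 20st + 10 t	332.52	0.34	66	1
outgroup	Mycetomoellerius holmgreni	10	20	Brazil	20 m	322.74	0.33	40	1
outgroup	Mycetomoellerius iheringi	10	20	Brazil	20 m	391.2	0.40	40	1
outgroup	Trachymyrmex septentrionalis	10	20	Panama	20 m	244.5	0.25	40	1
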