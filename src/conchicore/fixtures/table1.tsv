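# Annotation table of the 47 single-frame shell-matrix-protein contigs
# (transcribed reference values: contig id, FPKM, best BLAST annotation, e-value).
contig_id	fpkm	annotation	evalue
contig_130	73.5	None	
contig_145	140864.70	None	
contig_171	2072.40	Sushi-like protein [Mytilus coruscus]	3.00e-21
contig_175	2671.90	None	
contig_218	29476.20	None	
contig_605	321.6	EGF-like domain-containing protein 2 isoform X3 [Octopus bimaculoides]	2.00e-107
contig_737	41106.30	None	
contig_749	175497.30	None	
contig_790	97350.2	None	
contig_835	862.5	CD109 Antigen-like isoform X1 [Crassostrea gigas]	0
contig_872	88.1	Chorion Peroxidase-like [Octopus vulgaris]	3.00e-45
contig_1003	2305.10	protein PFC0760c-like [Octopus vulgaris]	1.00e-3
contig_1132	1428.80	Phospholipase A2-like [Centruroides sculpturatus]	1.00e-39
contig_1391	239	hypothetical protein KP79_PYT17609 [Mizuhopecten yessoensis]	6.00e-10
contig_1429	1.9	None	
contig_2249	6547	Aplysianin-A-like [Crassostrea virginica]	9.00e-6
contig_2301	77909.50	hypothetical protein LOTGIDRAFT_176428 [Lottia gigantea]	3.00e-8
contig_2437	224.1	Chitinase [Sepia esculenta]	2.00e-42
contig_3214	1694.2	hypothetical protein LOTGIDRAFT_236297 [Lottia gigantea]	1.00e-4
contig_3983	1112.5	None	
contig_4501	663.3	Papilin-like [Lingula anatina]	2.00e-37
contig_6305	420.8	uncharacterized protein LOC112560033 isoform X3 [Pomacea canaliculata]	2.00e-24
contig_6751	2281.00	BMSP [Mytilus galloprovincialis]	3.00e-19
contig_7092	93.4	Collagen Alpha-3(VI) chain isoform X2 [Cricetulus griseus]	6.00e-8
contig_7381	440	hypothetical protein OCBIM_22014960mg [Octopus bimaculoides]	3.00e-51
contig_8396	288.3	Sushi-like protein [Mytilus coruscus]	6.00e-56
contig_8398	6029.2	None	
contig_11910	1079.4	PREDICTED: nucleobindin-1-like, partial [Paralichthys olivaceus]	2.00e-7
contig_13424	197.6	Heme-binding protein 2-like [Limulus polyphemus]	3.00e-8
contig_14184	431.7	Peroxidase-like protein [Mizuhopecten yessoensis]	9.00e-42
contig_14880	772.8	None	
contig_16223	267.3	None	
contig_17506	164.2	Protein PIF [Mizuhopecten yessoensis]	1.00e-2
contig_21095	770.1	None	
contig_21964	195.5	None	
contig_23085	71.3	None	
contig_25822	83.8	hypothetical protein KP79_PYT14004 [Mizuhopecten yessoensis]	9.00e-8
contig_30055	123.8	uncharacterized protein LOC106876168 [Octopus bimaculoides]	3.00e-18
contig_30170	134.5	Mucin-5AC-like isoform X2 [Pomacea canaliculata]	4.00e-15
contig_30322	109.8	None	
contig_33774	152.2	None	
contig_34307	12.1	Collagen-like protein-1, partial [Mytilus coruscus]	3.00e-13
contig_35294	13.7	None	
contig_38157	3.4	Tyrosinase-like protein [Octopus vulgaris]	3.00e-77
contig_38801	167	None	
contig_46079	0	None	
contig_46877	59.3	hypothetical protein LOTGIDRAFT_169029 [Lottia gigantea]	3.00e-3
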