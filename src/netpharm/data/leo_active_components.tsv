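Time	CID No	Name	Formula	Canonical SMILES	MW	Drug likeness (DL)	GI absorption (OB)	P-gp substrate	BBB
14.61	562380	1,4-Methano-1H-cyclopenta[d]pyridazine, 4,4a,5,7a-tetrahydro-8,8-dimethyl-, (1.alpha.,4.alpha.,4a.alpha.,7a.alpha.)-	C10H14N2	CC1(C2C3CC=CC3C1NN2)C	162	Yes; 0 violation	High	No	Yes
	576686	2-Pyrazoline-3-carboxylic acid, 5-hydroxy-1-(4-methylbenzoyl)-5-phenyl-, methyl ester	C19H18N2O4	COC(=O)C1NN(C(=O)C2CCC(C)CC2)C(O)(C1)C1CCCCC1	338	Yes; 0 violation	High	No	No
15.25	64243	8-Methylenebicyclo[4.2.0]oct-4-en-3-one	C9H10O	CC1CC2CCC(=O)CC12	134	Yes; 0 violation	High	No	Yes
16.45	609873	3-Thiazolidinecarboxylic acid, 4-(acetyloxy)-2-(1,1-dimethylethyl)-, phenylmethyl ester, 1-oxide, [1R-(1.alpha.,2.beta.,4.beta.)]-	C17H23NO5S	CC(=O)OC1CS(=O)C(N1C(=O)OCC2CCCCC2)C(C)(C)C	353	Yes; 0 violation	High	No	No
	522804	4-Benzyloxyphenylacetonitrile	C15H13NO	C1CCC(CC1)COC2CCC(CC2)CC#N	223	Yes; 0 violation	High	No	Yes
17.25	557603	3,10-Dioxatricyclo[4.3.1.0(2,4)]dec-7-ene	C8H10O2	C1CCC2CC3OC3C1O2	138	Yes; 0 violation	High	No	Yes
	544156	Acrylic acid 5-methylidene-6-heptenyl ester	C11H16O2	CCC(=C)CCCCOC(=O)CC	180	Yes; 0 violation	High	No	Yes
18.25	56420	Spiro[cyclopropane-1,6'-[3]oxatricyclo[3.2.1.0(2,4)]octane]	C9H12O	C1CC11CC2CC1C1OC21	136	Yes; 0 violation	High	No	Yes
	6673	Dicyclopentadiene diepoxide	C10H12O2	C1C2C3CC4C(C3C1C5C2O5)O4	164	Yes; 0 violation	High	No	Yes
18.62	49955570	7,8-Diazabicyclo[4.2.2]deca-2,4,7,9-tetraen-7-oxide	C8H8N2O	ON1NC2CCC1\CC/CC\2	148	Yes; 0 violation	High	Yes	Yes
19.88	556274	Bicyclo[2.2.1]hept-5-en-2-yl-acetaldehyde	C9H12O	[H]C(=O)CC1CC2CC1CC2	136	Yes; 0 violation	High	No	Yes
	572048	3-Caren-10-al	C10H14O	CC1(C2C1CC(=CC2)CO)C	150	Yes; 0 violation	High	No	Yes
23.94	561932	beta-Terpinyl acetate	C12H20O2	CC(=C)C1CCC(CC1)(C)OC(=O)C	196	Yes; 0 violation	High	No	Yes
29.96	61275	Nerol oxide/2H-Pyran, 3,6-dihydro-4-methyl-2-(2-methyl-1-propenyl)-	C10H16O	CC1CCOC(C1)CC(C)C	152	Yes; 0 violation	High	No	Yes
	10819	Perillyl alcohol/1-Cyclohexene-1-methanol, 4-(1-methylethenyl)-	C10H16O	CC(=C)C1CCC(=CC1)CO	152	Yes; 0 violation	High	No	Yes
	561502	Phenylacetic acid, dodec-9-ynyl ester	C20H28O2	CCC#CCCCCCCCCOC(=O)CC1CCCCC1	300	Yes; 1 violation	High	No	Yes
34.95	561486	Tricyclo[4.2.1.0(2,5)]non-7-en-3-one	C9H10O	OC1CC2C1C1CC2CC1	134	Yes; 0 violation	High	No	Yes
36.17	2440052	2-(2-Methylphenyl)propan-2-ol	C10H14O	CC1CCCCC1C(C)(C)O	150	Yes; 0 violation	High	No	Yes
48.55	55304	alpha.-Phenethyl cyanide, 2-methoxy-6-nitro-	C10H10N2O3	CC(C#N)C1C(CCCC1OC)[N+](=O)[O-]	206	Yes; 0 violation	High	No	Yes
	535386	Bicyclo[4.4.0]dec-5-ene, 1,5-dimethyl-3-hydroxy-8-(1-methylene-2-hydroxyethyl-1)-	C15H24O2	CC1C2CC(CCC2(C)CC(O)C1)C(=C)CO	236	Yes; 0 violation	High	No	Yes
	543063	Sericealactone (5-Benzofuranacetic acid, 2,4,5,6,7,7a-hexahydro-7a-hydroxy-3,6-dimethyl-.alpha.-methylene-2-oxo-6-vinyl-, methyl ester)	C16H20O5	CC1C2CC(C(CC2(OC1O)O)(C)CC)C(=C)C(=O)OC	292	Yes; 0 violation	High	No	Yes
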