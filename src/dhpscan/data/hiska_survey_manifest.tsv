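pdb_id	protein	ph	rotamers	mother_liquor
3DGE	HK853	5.6	trans/trans	1.7 M (NH4)2SO4, 2.5% dioxane, 0.1 M citrate, pH 5.6
5UHT	HK853	5.0	gauche-/gauche-	0.1 M citric acid (pH 4), 0.8 M NH4SO4. Adjusted final pH to 5.0
2C2A	HK853	6.5	gauche-/gauche-	1.25 M Li2SO4, 0.1 M NH4 acetate pH 6.5
4JAU	HK853	8.5	gauche-/trans	8% PEG4000, 0.8 M LiCl2, 0.1 M Tris-HCl pH 8.5
4JAS	HK853	5.5	gauche-/gauche-	2.2 M (NH4)2SO4, 0.1 M Bis-Tris pH 5.5
4JAV	HK853	5.5	gauche-/gauche- & trans	2.2 M (NH4)2SO4, 0.1 M Bis-Tris pH 5.5
4I5S	VicK	7.6-8.6	trans/gauche-	2.3-2.9 M Na formate, 3% PEG 4000
4U7N	WalK	5.6	gauche-/trans	1.0 M (NH4)2SO4, 1% PEG 4000, 50 mM Bis-Tris pH 5.6
5C93	WalK	5.6	gauche- & trans/trans	1.0 M (NH4)2SO4, 1% PEG 4000, 50 mM Bis-Tris pH 5.6
4U7O	WalK	5.6	trans/trans	1.0 M (NH4)2SO4, 1% PEG 4000, 50 mM Bis-Tris pH 5.6
4ZKI	WalK	5.6	trans/gauche-	1.0 M (NH4)2SO4, 1% PEG 4000, 50 mM Bis-Tris pH 5.6
3ZRV	EnvZ-HAMP-DHp	7.0	trans/trans	20% PEG 4000, 20% Isopropanol, 0.1 M tri-sodium citrate pH 5.6
3ZRX	EnvZ-HAMP-DHp	4.6	trans/trans	30% MPD, 0.02 M CaCl2, 0.1 M sodium acetate
3ZRW	EnvZ-HAMP-DHp	7.0	trans/trans	0.4 M Mg formate, 0.1 M Bis-Tris, pH 7
5B1N	EnvZ-DHp	6.9	trans/trans	1.1-1.3 M Na/K phosphate
5B1O	EnvZ-DHp	6.9	trans/trans	0.1 M magnesium formate, 15% PEG 3350
4KP4	EnvZ-chim	7.5	trans/trans	1.5 M (NH4)2SO4, 2% PEG 1000, 2% PEG 4000, 0.03 M Na acetate, 0.1 M HEPES pH 7.5
4BIU	CpxA	8.5	trans/trans	1.75 M (NH4)2SO4, 25% glycerol, 0.1 M Tris-HCl pH 8.5
4BIW	CpxA	8.5	trans/gauche-	1.75 M (NH4)2SO4, 25% glycerol, 0.1 M Tris-HCl pH 8.5
5LFK	CpxA	8.5	trans/trans	1.5 M (NH4)2SO4, 12% glycerol, 0.1 M Tris-HCl pH 8.5
4BIV	CpxA	8.5	trans/gauche-	1.75 M (NH4)2SO4, 25% glycerol, 0.1 M Tris-HCl pH 8.5
4CB0	CpxA	8.5	trans/gauche-	1.75 M (NH4)2SO4, 25% glycerol, 0.1 M Tris-HCl pH 8.5
4BIX	CpxA	8.5	gauche-/gauche-	25% PEG3350, 0.2 M Li2SO4, 0.1 M Tris-HCl pH 8.5
4BIY	CpxA	8.5	gauche-/gauche-	25% PEG3350, 0.2 M Li2SO4, 0.1 M Tris-HCl pH 8.5
4CTI	EnvZ-HAMP-Af1503	4.0	trans/trans/trans/trans	20% PEG 3350, 0.2 M lithium acetate, 0.1 M MMT buffer pH 4.0
5UKV	PhoR-DHp	7.2	gauche-/gauche-	35% PEG 200, 2 mM EDTA, 0.2 M KI, 0.1 M Na/K phosphate pH 7.2
4MT8	ERS1-DHp	7.5	gauche-/trans	9% PEG 3350, 0.18 M L-proline, 0.1 M HEPES pH 7.5
6DK7	RetS-DHp-CA	7.5	trans/trans/trans/trans/gauche-/gauche-/gauche-/gauche-	2.7 M NaCl, 9 mM CoCl2, 90 mM HEPES pH 7.5
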