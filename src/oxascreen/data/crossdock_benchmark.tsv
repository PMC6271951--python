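# Cross-docking benchmark against E. coli BC complexed with ADP:
# ligand heavy-atom RMSD (angstroms) of the redocked pose from the
# corresponding crystal structure, for AutoDock Vina and eSimDock.
pdb_id	scaffold	vina_rmsd	esimdock_rmsd
1dv2	ATP	7.443	3.035
2v58	pyrido[3,2-d]pyrimidine	2.208	0.992
2v59	pyrido[3,2-d]pyrimidine	1.372	0.980
2v5a	pyrido[3,2-d]pyrimidine	6.729	1.670
2w6m	2-amino-oxazole	7.227	0.957
2w6n	2-amino-oxazole	0.348	4.432
2w6o	7,8-dihydroquinazoline	7.038	1.331
2w6p	quinazoline	7.127	2.230
2w6q	1,3,5-triazine	6.591	0.614
2w6z	3H-purine	5.880	0.317
2w70	pyrimidine	5.356	1.063
2w71	pyrimidine	0.481	3.007
3jzf	1H-benzimidazole	0.721	5.376
3jzi	1H-benzimidazole	8.515	6.917
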