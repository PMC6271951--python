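# Docking scores of five top-ranked amino-oxazole derivatives against the
# E. coli (Ec) and S. pneumoniae (Sp) BC isoforms: anchor RMSD (angstroms),
# eSimDock fitness/binding scores, predicted affinity (ln Ki), and the
# force-field interaction energy (kcal/mol).
compound_id	isoform	anchor_rmsd	affinity	fitness	binding	energy
ao-02168779-40448781-000	Ec	1.41	0.71	1.00	1.00	38.19
ao-02168779-40448781-000	Sp	1.42	0.79	1.00	1.00	50.52
ao-00388499-06125795-000	Ec	1.79	0.36	1.00	1.00	40.68
ao-00388499-06125795-000	Sp	1.84	-0.05	1.00	0.91	4.30
ao-00900729-40448504-000	Ec	1.93	-0.12	1.00	0.99	37.96
ao-00900729-40448504-000	Sp	1.92	0.55	1.00	0.96	20.95
ao-02149727-15042121-000	Ec	1.81	0.22	1.00	1.00	84.23
ao-02149727-15042121-000	Sp	1.82	0.57	1.00	0.99	32.37
ao-00403318-01672846-002	Ec	1.83	-0.45	1.00	1.00	89.74
ao-00403318-01672846-002	Sp	1.83	0.39	1.00	0.99	34.06
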