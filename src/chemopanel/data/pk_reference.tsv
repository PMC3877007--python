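# Clinical exposure reference for antimalarial drug candidates.
# Ranged literature values are stored as midpoints; blank = not reported.
compound	dose	cmax_ng_ml	auc_ng_h_ml	half_life_h	source
OZ439	50 mg capsule	17	102		Moehrle
OZ439	100 mg capsule	34	249		Moehrle
OZ439	200 mg capsule	102	890		Moehrle
OZ439	400 mg capsule	135	1130		Moehrle
OZ439	800 mg capsule	315	3010	27.9	Moehrle
OZ439	1200 mg capsule	701	6530	31.6	Moehrle
OZ439	400 mg dispersion	566	5430	31.2	Moehrle
OZ439	800 mg dispersion	917	9630	25.2	Moehrle
OZ439	1600 mg dispersion	1340	17500	30.7	Moehrle
OZ439	800 mg dispersion (fed)	2400			Moehrle
OZ439	800-1200 mg dispersion	1600			Moehrle
OZ277	50 mg	8	40		Valecha
OZ277	100 mg	19	105		Valecha
OZ277	200 mg	41	239		Valecha
OZ277	50 mg (repeat)	14	79		Valecha
OZ277	100 mg (repeat)	25	152		Valecha
OZ277	200 mg (repeat)	68	408		Valecha
ART	120 mg iv	15350	957	0.042	Morris
DHA	120 mg iv ART, DHA readout	2130	2572	0.68	Morris
ART	200 mg po	93	162		Morris
DHA	200 mg po ART, DHA readout	654	1229		Morris
ART	120 mg im	884	999	0.68	Morris
DHA	120 mg im ART, DHA readout	1166	2474	1.07	Morris
ART	120 mg ir	448	796	0.95	Morris
DHA	120 mg ir ART, DHA readout	219	965	1.2	Morris
DHA	40 mg	39	98		-
ART	60 mg	183	155		-
artemisone	10 mg po	40	30	33.5	Nagelschmitz
artemisone	20 mg po	57	66		Nagelschmitz
artemisone	30 mg po	51	72		Nagelschmitz
artemisone	40 mg po	83	118		Nagelschmitz
artemisone	80 mg po	140	282		Nagelschmitz
pyrimethamine	75 mg po		36550		Green
pyrimethamine	50 mg/d, 3 wk	2059	41800	191	Jacobson
pyrimethamine	75 mg single dose	800	106065		Karunajeewa
pyrimethamine	25 mg single dose	760	76000	114	Mansor
P218	rat 30 mg/kg	6257		7.3	Yuthavong
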