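patient_id	sex	ascertainment	karyotype	rearrangement_class	del_size	associated_imbalance	repair_mechanism	parental_origin	mosaic_percent
P1	M	Tel-FISH	Del(22)(q13.3)dn	Terminal deletion	0.9 Mb		Telomere healing	Pat
P2	F	K	Del(22)(q13.31)dn	Terminal deletion	5.38 Mb		Telomere capture	Pat
P3	F	Tel-FISH	Del(22)(q13.32)dn	Terminal deletion	2.5 Mb		Telomere healing	Mat
P4	M	Tel-FISH	Del(22)(q13.32)dn	Terminal deletion	1.64 Mb		Telomere healing	U
P5	F	K	Del(22)(q13.31)dn	Terminal deletion	6.5 Mb		Telomere healing	Pat
P6	M	Tel-FISH	Del(22)(q13.32)dn	Terminal deletion	2.65 Mb		Telomere healing	Mat
P7	F	Tel-FISH	Del(22)(q13.31)dn	Terminal deletion	3.5 Mb		Telomere healing	Mat
P8	M	K	Del(22)q(13.32)dn	Terminal deletion	8.1 Mb		Telomere healing	Pat
P9	M	Tel-FISH	Del(22)(q13.31)dn	Terminal deletion	0.8 Mb			Pat
P10	F	K	Del(22)(q13.2)dn	Terminal deletion	8.1 Mb			U
P12	F	aCGH	Del(22)(q13.31)dn	Terminal deletion	4.98 Mb		Telomere healing	Pat
P13	F	aCGH	Del(22)(q13.3)dn	Terminal deletion	1.08 Mb		Telomere healing	U
P14	F	K	Del(22)q(13.31)dn	Terminal deletion	5.8 Mb		Telomere healing	U
P17	M	K	Del(22)(q13.2)dn	Terminal deletion	7.6 Mb			Pat
P18	F	Tel-FISH	Del(22)(q13.31)dn	Terminal deletion	4.7 Mb			U
P19	M	Tel-FISH	Del(22)(q13)dn	Terminal deletion	3.7 Mb			U
P20	F	K	Del(22)q(13.2q13.3)dn	Terminal deletion	7.2 Mb		Telomere healing	Pat
P21	F	Tel-FISH	Del(22)(q13.31)dn	Terminal deletion	4.7 Mb		Telomere healing	Mat
P22	F	Tel-FISH	Del(22)(q13.32)dn	Terminal deletion	1.9 Mb			Mat
P23	M	aCGH	Del(22)(q13.31)dn	Terminal deletion	3.4 Mb			Pat
P24	F	aCGH	Del(22)(q13.32)dn	Terminal deletion	1.8 Mb			Pat
P30	F	aCGH	Del(22)(q13.31)	Terminal deletion	3.4 Mb		Telomere healing	Pat
P31	M	Tel-MLPA,aCGH	Del(22)(q13.33)dn	Terminal deletion	122,392 bp		Telomere healing	Pat
P32	F	aCGH	Del(22)(q13.33)dn	Terminal deletion	122,388 bp		Telomere healing	Pat
P34	M	Tel-FISH	Del(22)(q13.31)dn	Terminal deletion	4.4 Mb		Telomere healing	Pat
P35	M	Tel-FISH	Del(22)(q13.31)dn	Terminal deletion	~4 Mb			U
P36	F	K	Del(22)(q13.2)dn mosaic 75%	Terminal deletion	9.0 Mb		Telomere healing	Pat	75
P39	M	aCGH	Del(22)(q13.3q13.3)	Terminal deletion	122,498 bp		Telomere capture	Pat
P40	F	K	Del(22)(q13.2q13.3)	Terminal deletion	7.4 Mb		Telomere capture	Mat
P41	F	K	Del(22)(q13.31q13.3)	Terminal deletion	5.8 Mb			Pat
P37	F	aCGH	Del(22)(q13.3q13.3)	Interstitial deletion	73,833 bp		NHEJ	Pat
P38	F	aCGH	Del(22)(q13.3q13.3)	Interstitial deletion	44,174 bp		NHEJ	Pat
P42	M	aCGH	Del(22)(q13.3q13.3)	Interstitial deletion	17,626 bp		FoSTeS	U
P43	F	aCGH	Del(22)(q13.3q13.3)	Interstitial deletion	26,914 bp		NHEJ	U
P44	M	aCGH	Del(22)(q13.3q13.3)	Interstitial deletion	38,948 bp		NHEJ	U
P25	F	K	Del(22)(q13.32)dn	Ring 22	2.16 Mb			Pat
P26	F	K	Del(22)(q13.33)dn	Ring 22	1.2 Mb		NHEJ	U
P27	M	K	Del(22)(q13.31)dn	Ring 22	5.2 Mb			Mat
P28	F	K	Del(22)q(13.33)dn	Ring 22	0.45 Mb	Dup(22)(q11-q13.23), 18 Mb; Dup(22)(q12.3-q13.2), 4.2 Mb		Mat
P29	M	K	Del(22)(q13.31)dn mosaic 30%	Ring 22	3.2 Mb			Pat	30
P33	M	K	Del(22)(q13.32)dn	Ring 22	2.04 Mb			Pat
P15	F	K	Del(22)(q31.31)mat	Derivative chromosome	4.3 Mb	Dup(12q24.33qter), 0.503 Mb	NHEJ	Mat
P16	M	K	Del(22)(q31.31)mat	Derivative chromosome	4.3 Mb	Dup(12q24.33qter), 0.503 Mb	NHEJ	Mat
P11	F	K	Del(22)(q13.31)pat	Derivative chromosome	5 Mb	Dup(12q24.32qter), 5.7 Mb	NHEJ	Pat
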