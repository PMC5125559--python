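# Eight amino-acid property scales used for Moran autocorrelation descriptors.
# Values are raw (unnormalized) AAindex entries; they are z-score normalized
# over the 20 residues before use.  version: 1
scale	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
hydrophobicity	0.02	-0.42	-0.77	-1.04	0.77	-1.10	-1.14	-0.80	0.26	1.81	1.14	-0.41	1.00	1.35	-0.09	-0.97	-0.77	1.71	1.11	1.13
flexibility	0.357	0.529	0.463	0.511	0.346	0.493	0.497	0.544	0.323	0.462	0.365	0.466	0.295	0.314	0.509	0.507	0.444	0.305	0.420	0.386
polarizability	0.046	0.291	0.134	0.105	0.128	0.180	0.151	0.000	0.230	0.186	0.186	0.219	0.221	0.290	0.131	0.062	0.108	0.409	0.298	0.140
free_energy	-0.368	-1.03	0.0	2.06	4.53	0.731	1.77	-0.525	0.0	0.791	1.07	0.0	0.656	1.06	-2.24	-0.524	0.0	1.60	4.91	0.401
residue_asa	115.0	225.0	160.0	150.0	135.0	180.0	190.0	75.0	195.0	175.0	170.0	200.0	185.0	210.0	145.0	115.0	140.0	255.0	230.0	155.0
residue_volume	52.6	109.1	75.7	68.4	68.3	89.7	84.7	36.3	91.9	102.0	102.0	105.1	97.7	113.9	73.6	54.9	71.2	135.4	116.2	85.1
steric	0.52	0.68	0.76	0.76	0.62	0.68	0.68	0.00	0.70	1.02	0.98	0.68	0.78	0.70	0.36	0.53	0.50	0.70	0.70	0.76
mutability	100.0	65.0	134.0	106.0	20.0	93.0	102.0	49.0	66.0	96.0	40.0	56.0	94.0	41.0	56.0	120.0	97.0	18.0	41.0	74.0
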