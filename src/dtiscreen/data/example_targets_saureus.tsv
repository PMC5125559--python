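# Worked-example prioritization input: subgraph and betweenness centrality
# values for ten reviewed proteins of methicillin-resistant S. aureus COL,
# as produced by centrality analysis of its STRING interactome.  version: 1
protein_id	sc	bc
SACOL2213	1.85E+23	0.0329
SACOL0591	2.76E+23	0.0198
SACOL0588	1.17E+23	0.0178
SACOL2675	1.01E+23	0.0128
SACOL1292	2.65E+23	0.0112
SACOL0593	2.82E+23	0.0093
SACOL2234	3.29E+23	0.0049
SACOL2233	3.11E+23	0.0047
SACOL2207	2.94E+23	0.0046
SACOL0545	1.06E+23	0.0045
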