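# Synthetic stand-in for the replication-set CDKN1A mutation list: the four
# additional CDKN1A-mutant tumours found on targeted re-sequencing of the
# replication cohort.  Published counts are preserved (six CDKN1A-mutant
# cancers in the full set, two of them with LOH, one of which is discovery
# tumour 745); the replication sample identifiers and positions here are
# placeholders, not the real ones.
tumour	gene	loh
R1	CDKN1A	1
R2	CDKN1A	0
R3	CDKN1A	0
R4	CDKN1A	0
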