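# Same-tRNA codon pairs in S. cerevisiae, grouped by the anticodon first
# (position-34) base.  codon_wc pairs by Watson-Crick (or I:C, the stronger
# wobble, for inosine anticodons); codon_wb is the wobble partner.
pair_class	codon_wc	codon_wb
U:A-vs-U:G	CAA	CAG
U:A-vs-U:G	AAA	AAG
U:A-vs-U:G	GAA	GAG
G:C-vs-G:U	UUC	UUU
G:C-vs-G:U	UAC	UAU
G:C-vs-G:U	CAC	CAU
G:C-vs-G:U	AAC	AAU
G:C-vs-G:U	GAC	GAU
G:C-vs-G:U	UGC	UGU
G:C-vs-G:U	AGC	AGU
G:C-vs-G:U	GGC	GGU
I:C-vs-I:U	GCC	GCU
I:C-vs-I:U	CGC	CGU
I:C-vs-I:U	AUC	AUU
I:C-vs-I:U	CUC	CUU
I:C-vs-I:U	CCC	CCU
I:C-vs-I:U	UCC	UCU
I:C-vs-I:U	ACC	ACU
I:C-vs-I:U	GUC	GUU
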