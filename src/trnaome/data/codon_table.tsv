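# Standard genetic code (NCBI translation table 1), DNA alphabet, v1
AAA	Lys
AAC	Asn
AAG	Lys
AAT	Asn
ACA	Thr
ACC	Thr
ACG	Thr
ACT	Thr
AGA	Arg
AGC	Ser
AGG	Arg
AGT	Ser
ATA	Ile
ATC	Ile
ATG	Met
ATT	Ile
CAA	Gln
CAC	His
CAG	Gln
CAT	His
CCA	Pro
CCC	Pro
CCG	Pro
CCT	Pro
CGA	Arg
CGC	Arg
CGG	Arg
CGT	Arg
CTA	Leu
CTC	Leu
CTG	Leu
CTT	Leu
GAA	Glu
GAC	Asp
GAG	Glu
GAT	Asp
GCA	Ala
GCC	Ala
GCG	Ala
GCT	Ala
GGA	Gly
GGC	Gly
GGG	Gly
GGT	Gly
GTA	Val
GTC	Val
GTG	Val
GTT	Val
TAA	STOP
TAC	Tyr
TAG	STOP
TAT	Tyr
TCA	Ser
TCC	Ser
TCG	Ser
TCT	Ser
TGA	STOP
TGC	Cys
TGG	Trp
TGT	Cys
TTA	Leu
TTC	Phe
TTG	Leu
TTT	Phe
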