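role	kind	anchor	pattern
precursor_rmlA	cwps	1	glucose-1-phosphate thymidylyltransferase|\brmlA\b
precursor_rmlB	cwps	1	dTDP-glucose 4,6-dehydratase|\brmlB\b
precursor_rmlC	cwps	1	dTDP-4-dehydrorhamnose 3,5-epimerase|\brmlC\b
precursor_rmlD	cwps	1	dTDP-4-dehydrorhamnose reductase|\brmlD\b
rhamnosyltransferase	cwps	1	rhamnosyltransferase|\brgp[ABEF]\b
abc_transporter	cwps	1	\brgp[CD]\b
modification_oxidoreductase	any	0	talose 4-dehydrogenase|dehydrogenase|oxidoreductase
transposase	any	0	transposase|\bIS\d+\b|insertion sequence
regulator	eps	1	\beps[RB]\b|transcriptional regulator|tyrosine-protein kinase|protein-tyrosine phosphatase|phosphoregulatory
eps_conserved	eps	1	\beps[ACDEX]\b|capsular polysaccharide biosynthesis protein|polysaccharide export protein|polysaccharide biosynthesis initiation
eps_terminal	eps	1	\bepsL\b|\borfY\b|polysaccharide biosynthesis modulator
abc_transporter	any	0	polysaccharide ABC transporter|teichoic acid export ATP-binding|capsular polysaccharide transport
priming_gt	cwps	1	priming glycosyltransferase|undecaprenyl-phosphate.*(glycosyl|galactose|glucose).*transferase|glycosylphosphotransferase|\bwpsA\b|\bycbB\b
membrane_anchor	cwps	0	polysaccharide biosynthesis membrane protein|\bwpsB\b
flippase	any	0	flippase|\bwzx\b|oligosaccharide translocase|polysaccharide biosynthesis protein
polymerase	any	0	repeat unit polymerase|oligosaccharide polymerase|\bwzy\b
copolymerase	any	0	polysaccharide copolymerase|chain length determinant
modification_acetylase	any	0	acetyltransferase|acetylase|\bOafA\b
modification_epimerase	any	0	NAD-dependent epimerase|UDP-glucose 4-epimerase|epimerase
modification_dehydratase	any	0	dehydratase
modification_other	any	0	sulfatase|phosphotransferase|mutase|aminotransferase|pyruvyl transferase
glycosyltransferase	any	0	glycosyltransferase|glycosyl transferase
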