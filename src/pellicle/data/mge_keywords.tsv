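category	pattern
transposase	transposase|\bIS\d+\b|insertion sequence
integrase	integrase|site-specific recombinase|tyrosine recombinase
phage	phage|prophage|capsid|tail protein|terminase|portal protein|holin|antirepressor
relaxase	relaxase|\bMobA\b|mobilization protein|\bMob[CQ]?\b
t4ss	type IV secretion|\bVirB\d*\b|\bVirD4\b(?! coupling)|conjugative transfer system
t4cp	type IV coupling|coupling protein|\bTraG\b|\bTcpA\b
conjugal	conjugal transfer|conjugation protein|\bTra[A-Z]\b
defense	abortive infection|\bAbi[A-Z]\b|restriction.modification|phage defense|toxin-antitoxin
amr	enterocin.*immunity|bacteriocin immunity|antimicrobial resistance|multidrug resistance
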