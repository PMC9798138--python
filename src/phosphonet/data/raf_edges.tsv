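parent	child
plcg	pip2
plcg	pip3
pip3	pip2
pip2	pkc
pip3	akt
pkc	pka
pkc	raf
pkc	mek
pkc	jnk
pkc	p38
pka	raf
pka	mek
pka	erk
pka	akt
pka	jnk
pka	p38
raf	mek
mek	erk
erk	akt
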