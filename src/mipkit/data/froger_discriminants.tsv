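# Froger P1-P5 discriminant residue sets (editable).
# Consensus as reproduced across the aquaporin literature: glycerol
# facilitators carry an aromatic P1, Asp P2, Lys/Arg P3, Pro P4 and a
# non-aromatic P5; water-selective aquaporins carry small P1-P3 and
# aromatic P4-P5.  Edit and pass the file path to FrogerTable.load() to
# override; the version string is stamped into every emitted profile.
position	aquaporin_allowed	glp_allowed
__version__	mipkit-consensus-1	.
P1	TSA	FYW
P2	SAT	D
P3	AGS	KR
P4	FYW	P
P5	WYF	LIVAM
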