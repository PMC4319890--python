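# Default pharmacophoric atom-typing mask.
# One rule per line: SMARTS<TAB>channel<TAB>+|-
# Rules are applied in order; later rules override earlier ones, so a
# channel can be opened broadly and then narrowed by exceptions.
#
# donor: N, O or S carrying at least one hydrogen
[#7;!H0]	donor	+
[#8;!H0]	donor	+
[#16;!H0]	donor	+
# acceptor: neutral N or O, plus fluorine; amide and pyrrole-type
# nitrogens are then withdrawn (their lone pair is delocalized)
[#7;+0]	acceptor	+
[#8;+0]	acceptor	+
[#9]	acceptor	+
[#7;$([#7][#6]=[#8])]	acceptor	-
[nX3]	acceptor	-
# hydrophobic: carbon or sulfur bonded only to C/S/halogen, and halogens
[#6;!$([#6]~[!#6;!#16;!#9;!#17;!#35;!#53])]	hydrophobic	+
[#16;!$([#16]~[!#6;!#16;!#9;!#17;!#35;!#53])]	hydrophobic	+
[#9,#17,#35,#53]	hydrophobic	+
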