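# Ballesteros-Weinstein marker residues used for featurization (author
# numbering of the human KOR construct; chain of the receptor).

[S153]
bw = "3.47"
chain = "A"
resnum = 153
resname = "SER"

[R156]
bw = "3.50"
chain = "A"
resnum = 156
resname = "ARG"

[Y330]
bw = "7.53"
chain = "A"
resnum = 330
resname = "TYR"
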