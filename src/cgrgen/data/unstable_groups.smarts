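# SMARTS patterns of likely unstable groups; one pattern per line, tab-separated name.
[SX4;H1](=O)	S_oxide_with_H
[SX3;H1](=O)	S_oxide_with_H
[PH1](=O)[OX2][#6]	H_phosphonate_ester
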