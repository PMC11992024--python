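# IIT (IFN/IL12-induced T cell) signature panel.
# The full signature comprises 22 genes distributed as a supplementary dataset
# of the originating study; only the members printed in the main text are
# pre-filled here. Replace or extend this file with the full list for real
# analyses (one gene symbol per line).
GZMA
GZMB
KLRG1
CD7
P2RX7
CCR5
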