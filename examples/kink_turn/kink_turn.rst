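# Core-position restraint template for the canonical kink-turn
# reference (1FFK chain 0). The match must include counterparts of the
# seven core positions: L1, -1b, -1n, 1b, 1n, 2b, 2n.
#
# Only two residue numbers below are published anchors: L1 = G94 and
# 1n = A80. The remaining five are placeholders for the neighbouring
# stem positions — replace them with the residue numbers of your own
# curated 14-residue module boundaries before running.
REQ 0/94 0/80
REQ 0/93 0/81 0/95 0/79 0/96   # placeholders: -1b -1n 1b 1n 2b-ish — EDIT ME
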