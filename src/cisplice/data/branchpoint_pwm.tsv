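# Branchpoint heptamer position probability matrix.
# Models the classical branch-site consensus TACTAAC with the branch
# adenosine at heptamer position 6 (1-based).  The consensus is kept
# deliberately strong so that branchpoint placement is well determined;
# override with --branch-pwm / branch_pwm config entry (same format) to
# use a more degenerate model.
# Columns: per-base foreground probabilities; rows: positions 5'->3'.
A	C	G	T
0.0167	0.0167	0.0166	0.95
0.95	0.0167	0.0167	0.0166
0.0167	0.95	0.0167	0.0166
0.0167	0.0167	0.0166	0.95
0.95	0.0167	0.0167	0.0166
0.96	0.0134	0.0133	0.0133
0.0167	0.90	0.0167	0.0666
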