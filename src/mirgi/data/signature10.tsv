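mirna	direction
mir-151	+
mir-301b	+
mir-505*	+
mir-324	+
mir-502	+
mir-421	+
let-7a*	-
mir-320	-
mir-146a*	-
mir-193a	-
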