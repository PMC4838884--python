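#module fate
#module fate_a_targets
#module fate_b_targets
#module survival
NODE	FateA	fate
NODE	FateB	fate
NODE	TgtA1	fate_a_targets
NODE	TgtA2	fate_a_targets
NODE	TgtB1	fate_b_targets
NODE	TgtB2	fate_b_targets
NODE	Surv	survival
NODE	Apop	survival
EDGE	FateA	FateA	+
EDGE	FateB	FateA	-
EDGE	FateB	FateB	+
EDGE	FateA	FateB	-
EDGE	FateA	TgtA1	+
EDGE	FateA	TgtA2	+
EDGE	FateB	TgtA2	-
EDGE	FateB	TgtB1	+
EDGE	FateB	TgtB2	+
EDGE	FateA	TgtB2	-
EDGE	FateA	Surv	+
EDGE	FateB	Surv	+
EDGE	Apop	Surv	-
EDGE	Apop	Apop	+
EDGE	Surv	Apop	-
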