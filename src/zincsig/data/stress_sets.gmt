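HEAT_SHOCK_RESPONSE	heat shock / chaperone induction	HSPA6	HSPA1A	HSPA1B	DNAJB1	DNAJA1	HSPB1	HSPH1
DNA_DAMAGE_STRESS	integrated stress / DNA damage response	DDIT3	GADD45A	ATF3	PPP1R15A	EGR1	JUN
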