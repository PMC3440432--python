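# Reaction mechanism: tissue-factor-initiated extrinsic cascade (base_extrinsic)
# plus the protein C pathway module (pc_pathway).
# Reversible rows ("<->") are expanded on load into an association (k_fwd) and a
# dissociation (k_rev) reaction sharing this row's id as reversible_pair_id.
reaction_id	lhs	arrow	rhs	k_fwd_id	k_rev_id	submodel
B01	TF + VII	<->	TF=VII	k2	k1	base_extrinsic
B02	TF + VIIa	<->	TF=VIIa	k4	k3	base_extrinsic
B03	TF=VIIa + VII	->	TF=VIIa + VIIa	k5		base_extrinsic
B04	Xa + VII	->	Xa + VIIa	k6		base_extrinsic
B05	IIa + VII	->	IIa + VIIa	k7		base_extrinsic
B06	TF=VIIa + X	<->	TF=VIIa=X	k9	k8	base_extrinsic
B07	TF=VIIa=X	->	TF=VIIa=Xa	k10		base_extrinsic
B08	TF=VIIa + Xa	<->	TF=VIIa=Xa	k12	k11	base_extrinsic
B09	TF=VIIa + IX	<->	TF=VIIa=IX	k14	k13	base_extrinsic
B10	TF=VIIa=IX	->	TF=VIIa + IXa	k15		base_extrinsic
B11	Xa + II	->	Xa + IIa	k16		base_extrinsic
B12	IIa + VIII	->	IIa + VIIIa	k17		base_extrinsic
B13	VIIIa + IXa	<->	IXa=VIIIa	k19	k18	base_extrinsic
B14	IXa=VIIIa + X	<->	IXa=VIIIa=X	k21	k20	base_extrinsic
B15	IXa=VIIIa=X	->	IXa=VIIIa + Xa	k22		base_extrinsic
B16	VIIIa1=L + VIIIa2	<->	VIIIa	k23	k24	base_extrinsic
B17	IXa=VIIIa=X	->	VIIIa1=L + VIIIa2 + X + IXa	k25		base_extrinsic
B18	IXa=VIIIa	->	VIIIa1=L + VIIIa2 + IXa	k25		base_extrinsic
B19	IIa + V	->	IIa + Va	k26		base_extrinsic
B20	Xa + Va	<->	Xa=Va	k28	k27	base_extrinsic
B21	Xa=Va + II	<->	Xa=Va=II	k30	k29	base_extrinsic
B22	Xa=Va=II	->	Xa=Va + mIIa	k31		base_extrinsic
B23	mIIa + Xa=Va	->	IIa + Xa=Va	k32		base_extrinsic
B24	Xa + TFPI	<->	Xa=TFPI	k34	k33	base_extrinsic
B25	TF=VIIa=Xa + TFPI	<->	TF=VIIa=Xa=TFPI	k36	k35	base_extrinsic
B26	TF=VIIa + Xa=TFPI	->	TF=VIIa=Xa=TFPI	k37		base_extrinsic
B27	Xa + AT	->	Xa=AT	k38		base_extrinsic
B28	mIIa + AT	->	mIIa=AT	k39		base_extrinsic
B29	IXa + AT	->	IXa=AT	k40		base_extrinsic
B30	IIa + AT	->	IIa=AT	k41		base_extrinsic
B31	TF=VIIa + AT	->	TF=VIIa=AT	k42		base_extrinsic
P01	IIa + Tm	<->	IIa=Tm	kp2	kp1	pc_pathway
P02	mIIa + Tm	<->	mIIa=Tm	kp2	kp1	pc_pathway
P03	IIa=Tm + PC	<->	IIa=Tm=PC	kp4	kp3	pc_pathway
P04	IIa=Tm=PC	->	IIa=Tm + APC	kp5		pc_pathway
P05	mIIa=Tm + PC	<->	mIIa=Tm=PC	kp4	kp3	pc_pathway
P06	mIIa=Tm=PC	->	mIIa=Tm + APC	kp5		pc_pathway
P07	IIa=Tm + AT	->	IIa=AT + Tm	kp6		pc_pathway
P08	mIIa=Tm + AT	->	mIIa=AT + Tm	kp6		pc_pathway
P09	APC + Va	<->	APC=Va	kp8	kp7	pc_pathway
P10	APC=Va	->	APC + Va5	kp9		pc_pathway
P11	APC=Va	->	APC + Va3	kp10		pc_pathway
P12	APC + Va5	<->	APC=Va5	kp8	kp7	pc_pathway
P13	APC=Va5	->	APC + Va53	kp11		pc_pathway
P14	APC + Va3	<->	APC=Va3	kp8	kp7	pc_pathway
P15	APC=Va3	->	APC + Va53	kp12		pc_pathway
P16	APC + VIIIa	<->	APC=VIIIa	kp8	kp7	pc_pathway
P17	APC=VIIIa	->	APC + VIIIai	kp13		pc_pathway
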