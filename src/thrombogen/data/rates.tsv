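# Rate constants for the thrombin generation model.
# All bimolecular constants have been converted from the source literature's
# M^-1 s^-1 to the engine unit nM^-1 s^-1 (divide by 1e9).
k_id	value	units	source_note
k1	3.1e-3	per_second	TF/VII dissociation
k2	3.2e-3	per_nanomolar_per_second	TF + VII association (3.2e6 /M/s)
k3	3.1e-3	per_second	TF/VIIa dissociation
k4	2.3e-2	per_nanomolar_per_second	TF + VIIa association (2.3e7 /M/s)
k5	4.4e-4	per_nanomolar_per_second	VII activation by TF=VIIa (4.4e5 /M/s)
k6	1.3e-2	per_nanomolar_per_second	VII activation by Xa (1.3e7 /M/s)
k7	2.3e-5	per_nanomolar_per_second	VII activation by IIa (2.3e4 /M/s)
k8	1.05	per_second	TF=VIIa=X dissociation
k9	2.5e-2	per_nanomolar_per_second	TF=VIIa + X association (2.5e7 /M/s)
k10	6.0	per_second	X activation within TF=VIIa=X
k11	19.0	per_second	TF=VIIa=Xa dissociation
k12	2.2e-2	per_nanomolar_per_second	TF=VIIa + Xa association (2.2e7 /M/s)
k13	2.4	per_second	TF=VIIa=IX dissociation
k14	1.0e-2	per_nanomolar_per_second	TF=VIIa + IX association (1.0e7 /M/s)
k15	1.8	per_second	IX activation within TF=VIIa=IX
k16	7.5e-6	per_nanomolar_per_second	II activation by free Xa (7.5e3 /M/s)
k17	2.0e-2	per_nanomolar_per_second	VIII activation by IIa (2.0e7 /M/s)
k18	5.0e-3	per_second	IXa=VIIIa dissociation
k19	1.0e-2	per_nanomolar_per_second	IXa + VIIIa association (1.0e7 /M/s)
k20	1.0e-3	per_second	IXa=VIIIa=X dissociation
k21	1.0e-1	per_nanomolar_per_second	IXa=VIIIa + X association (1.0e8 /M/s)
k22	8.2	per_second	X activation within IXa=VIIIa=X
k23	2.2e-5	per_nanomolar_per_second	VIIIa1=L + VIIIa2 reassociation (2.2e4 /M/s)
k24	6.0e-3	per_second	VIIIa spontaneous dissociation into subunits
k25	1.0e-3	per_second	VIIIa subunit loss within IXa=VIIIa(,=X)
k26	2.0e-2	per_nanomolar_per_second	V activation by IIa (2.0e7 /M/s)
k27	0.2	per_second	Xa=Va dissociation
k28	4.0e-1	per_nanomolar_per_second	Xa + Va association (4.0e8 /M/s)
k29	103.0	per_second	Xa=Va=II dissociation
k30	1.0e-1	per_nanomolar_per_second	Xa=Va + II association (1.0e8 /M/s)
k31	63.5	per_second	II activation to mIIa within prothrombinase
k32	1.5e-2	per_nanomolar_per_second	mIIa conversion to IIa by prothrombinase (1.5e7 /M/s)
k33	3.6e-4	per_second	Xa=TFPI dissociation
k34	9.0e-4	per_nanomolar_per_second	Xa + TFPI association (9.0e5 /M/s)
k35	1.1e-4	per_second	TF=VIIa=Xa=TFPI dissociation
k36	3.2e-1	per_nanomolar_per_second	TF=VIIa=Xa + TFPI association (3.2e8 /M/s)
k37	5.0e-2	per_nanomolar_per_second	TF=VIIa + Xa=TFPI association (5.0e7 /M/s)
k38	1.5e-6	per_nanomolar_per_second	Xa inhibition by AT (1.5e3 /M/s)
k39	7.1e-6	per_nanomolar_per_second	mIIa inhibition by AT (7.1e3 /M/s)
k40	4.9e-7	per_nanomolar_per_second	IXa inhibition by AT (4.9e2 /M/s)
k41	7.1e-6	per_nanomolar_per_second	IIa inhibition by AT (7.1e3 /M/s)
k42	2.3e-7	per_nanomolar_per_second	TF=VIIa inhibition by AT (2.3e2 /M/s)
kp1	5.0e-2	per_second	(m)IIa=Tm dissociation (Kd 0.5 nM)
kp2	1.0e-1	per_nanomolar_per_second	(m)IIa + Tm association (1.0e8 /M/s)
kp3	6.0	per_second	(m)IIa=Tm=PC dissociation
kp4	1.0e-2	per_nanomolar_per_second	(m)IIa=Tm + PC association (1.0e7 /M/s; Km 700 nM)
kp5	1.0	per_second	PC activation within (m)IIa=Tm=PC
kp6	1.6e-5	per_nanomolar_per_second	AT inhibition of Tm-bound (m)IIa (1.6e4 /M/s)
kp7	0.7	per_second	APC=cofactor Michaelis complex dissociation
kp8	1.0e-3	per_nanomolar_per_second	APC + cofactor association (1.0e6 /M/s, solution phase)
kp9	1.0	per_second	fast-site cleavage of Va within APC=Va
kp10	3.7e-2	per_second	slow-site cleavage of Va within APC=Va
kp11	0.192	per_second	slow-site cleavage of Va5 within APC=Va5
kp12	1.0	per_second	fast-site cleavage of Va3 within APC=Va3
kp13	0.5	per_second	VIIIa inactivation within APC=VIIIa
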