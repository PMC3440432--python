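# Species table for the tissue-factor-initiated thrombin generation model.
# Complexes are written with "=" between components; active enzymes carry an "a" suffix.
# moieties: semicolon-separated moiety:count pairs. The VIII zymogen is book-kept with
# two chain moieties (VIII = A1/light-chain portion, VIII2 = A2 domain) so that the
# spontaneous dissociation of VIIIa into VIIIa1=L and VIIIa2 conserves both.
symbol	display_name	moieties	submodel
TF	tissue factor	TF:1	base_extrinsic
VII	factor VII zymogen	VII:1	base_extrinsic
VIIa	factor VIIa	VII:1	base_extrinsic
TF=VII	tissue factor - factor VII complex	TF:1;VII:1	base_extrinsic
TF=VIIa	extrinsic tenase (TF-VIIa)	TF:1;VII:1	base_extrinsic
X	factor X zymogen	X:1	base_extrinsic
Xa	factor Xa	X:1	base_extrinsic
TF=VIIa=X	extrinsic tenase - factor X Michaelis complex	TF:1;VII:1;X:1	base_extrinsic
TF=VIIa=Xa	extrinsic tenase - factor Xa product complex	TF:1;VII:1;X:1	base_extrinsic
IX	factor IX zymogen	IX:1	base_extrinsic
IXa	factor IXa	IX:1	base_extrinsic
TF=VIIa=IX	extrinsic tenase - factor IX Michaelis complex	TF:1;VII:1;IX:1	base_extrinsic
II	prothrombin	II:1	base_extrinsic
IIa	thrombin	II:1	base_extrinsic
mIIa	meizothrombin	II:1	base_extrinsic
VIII	factor VIII zymogen	VIII:1;VIII2:1	base_extrinsic
VIIIa	factor VIIIa	VIII:1;VIII2:1	base_extrinsic
IXa=VIIIa	intrinsic tenase (IXa-VIIIa)	IX:1;VIII:1;VIII2:1	base_extrinsic
IXa=VIIIa=X	intrinsic tenase - factor X Michaelis complex	IX:1;VIII:1;VIII2:1;X:1	base_extrinsic
VIIIa1=L	factor VIIIa A1-light chain dimer	VIII:1	base_extrinsic
VIIIa2	factor VIIIa A2 domain	VIII2:1	base_extrinsic
V	factor V zymogen	V:1	base_extrinsic
Va	factor Va	V:1	base_extrinsic
Xa=Va	prothrombinase (Xa-Va)	X:1;V:1	base_extrinsic
Xa=Va=II	prothrombinase - prothrombin Michaelis complex	X:1;V:1;II:1	base_extrinsic
TFPI	tissue factor pathway inhibitor	TFPI:1	base_extrinsic
Xa=TFPI	factor Xa - TFPI complex	X:1;TFPI:1	base_extrinsic
TF=VIIa=Xa=TFPI	quaternary TF-VIIa-Xa-TFPI complex	TF:1;VII:1;X:1;TFPI:1	base_extrinsic
AT	antithrombin	AT:1	base_extrinsic
Xa=AT	factor Xa - antithrombin complex	X:1;AT:1	base_extrinsic
mIIa=AT	meizothrombin - antithrombin complex	II:1;AT:1	base_extrinsic
IXa=AT	factor IXa - antithrombin complex	IX:1;AT:1	base_extrinsic
IIa=AT	thrombin - antithrombin complex	II:1;AT:1	base_extrinsic
TF=VIIa=AT	extrinsic tenase - antithrombin complex	TF:1;VII:1;AT:1	base_extrinsic
Tm	thrombomodulin	Tm:1	pc_pathway
PC	protein C zymogen	PC:1	pc_pathway
APC	activated protein C	PC:1	pc_pathway
IIa=Tm	thrombin - thrombomodulin complex	II:1;Tm:1	pc_pathway
mIIa=Tm	meizothrombin - thrombomodulin complex	II:1;Tm:1	pc_pathway
IIa=Tm=PC	thrombin - thrombomodulin - protein C Michaelis complex	II:1;Tm:1;PC:1	pc_pathway
mIIa=Tm=PC	meizothrombin - thrombomodulin - protein C Michaelis complex	II:1;Tm:1;PC:1	pc_pathway
APC=Va	APC - factor Va Michaelis complex	PC:1;V:1	pc_pathway
Va5	factor Va cleaved at the fast (506-type) site	V:1	pc_pathway
Va3	factor Va cleaved at the slow (306-type) site	V:1	pc_pathway
Va53	factor Va cleaved at both inactivation sites	V:1	pc_pathway
APC=Va5	APC - Va5 Michaelis complex	PC:1;V:1	pc_pathway
APC=Va3	APC - Va3 Michaelis complex	PC:1;V:1	pc_pathway
APC=VIIIa	APC - factor VIIIa Michaelis complex	PC:1;VIII:1;VIII2:1	pc_pathway
VIIIai	APC-inactivated factor VIIIa	VIII:1;VIII2:1	pc_pathway
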