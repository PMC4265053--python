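# Canonical crtEBI neurosporene pathway, elementary reaction network, v1.
# One reversible elementary reaction per line: id, enzyme, overall conversion,
# reactants <-> products (species joined by ' + '; 'X:Y' denotes an
# enzyme-bound complex). Rate constant ids are kf_<id> / kr_<id>.
# Totals: 24 reversible reactions (48 rate constants), 10 overall conversions
# catalyzed by Idi, IspA, CrtE, CrtB, CrtI; 29 species (9 free metabolites,
# 5 free enzymes, 15 enzyme complexes). IPP and DMAPP are boundary precursor
# pools. Prephytoene (PPPP) occurs only enzyme-bound (processive CrtB).
# Cofactors are not modeled.
#
# id	enzyme	conversion	reactants	products	kind
R01	Idi	Idi.1	Idi + IPP	Idi:IPP	bind
R02	Idi	Idi.1	Idi:IPP	Idi:DMAPP	cat
R03	Idi	Idi.1	Idi:DMAPP	Idi + DMAPP	release
R04	IspA	IspA.1	IspA + DMAPP	IspA:DMAPP	bind
R05	IspA	IspA.1	IspA:DMAPP + IPP	IspA:GPP	cat
R06	IspA	IspA.1	IspA:GPP	IspA + GPP	release
R07	IspA	IspA.2	IspA:GPP + IPP	IspA:FPP	cat
R08	IspA	IspA.2	IspA:FPP	IspA + FPP	release
R09	CrtE	CrtE.1	CrtE + GPP	CrtE:GPP	bind
R10	CrtE	CrtE.1	CrtE:GPP + IPP	CrtE:FPP	cat
R11	CrtE	CrtE.1	CrtE:FPP	CrtE + FPP	release
R12	CrtE	CrtE.2	CrtE:FPP + IPP	CrtE:GGPP	cat
R13	CrtE	CrtE.2	CrtE:GGPP	CrtE + GGPP	release
R14	CrtB	CrtB.1	CrtB + GGPP	CrtB:GGPP	bind
R15	CrtB	CrtB.1	CrtB:GGPP + GGPP	CrtB:PPPP	cat
R16	CrtB	CrtB.2	CrtB:PPPP	CrtB:Phytoene	cat
R17	CrtB	CrtB.2	CrtB:Phytoene	CrtB + Phytoene	release
R18	CrtI	CrtI.1	CrtI + Phytoene	CrtI:Phytoene	bind
R19	CrtI	CrtI.1	CrtI:Phytoene	CrtI:Phytofluene	cat
R20	CrtI	CrtI.1	CrtI:Phytofluene	CrtI + Phytofluene	release
R21	CrtI	CrtI.2	CrtI:Phytofluene	CrtI:ZetaCarotene	cat
R22	CrtI	CrtI.2	CrtI:ZetaCarotene	CrtI + ZetaCarotene	release
R23	CrtI	CrtI.3	CrtI:ZetaCarotene	CrtI:Neurosporene	cat
R24	CrtI	CrtI.3	CrtI:Neurosporene	CrtI + Neurosporene	release
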