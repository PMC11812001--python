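id	name	mono_mass	classifications
1	Acetyl	42.010565	K=Post-translational;S=Post-translational;T=Post-translational;C=Post-translational;N-term=Multiple
2	Amidated	-0.984016	C-term=Post-translational
4	Carbamidomethyl	57.021464	C=Chemical derivative;K=Artefact;H=Artefact;D=Artefact;E=Artefact;S=Artefact;T=Artefact;Y=Artefact;M=Artefact;N-term=Artefact
5	Carbamyl	43.005814	K=Multiple;N-term=Multiple;R=Artefact;C=Artefact
7	Deamidated	0.984016	N=Artefact;Q=Artefact
21	Phospho	79.966331	S=Post-translational;T=Post-translational;Y=Post-translational;D=Post-translational;H=Post-translational;C=Post-translational;R=Post-translational;K=Post-translational
30	Cation:Na	21.981944	D=Artefact;E=Artefact;C-term=Artefact
34	Methyl	14.015650	K=Post-translational;R=Post-translational;C-term=Multiple;N-term=Multiple
35	Oxidation	15.994915	M=Artefact;W=Artefact;H=Artefact;F=Artefact;Y=Artefact;P=Post-translational;K=Post-translational;R=Post-translational;N=Post-translational;D=Post-translational;C=Post-translational
36	Dimethyl	28.031300	K=Post-translational;R=Post-translational;N-term=Multiple
37	Trimethyl	42.046950	K=Post-translational;R=Post-translational
40	Sulfo	79.956815	S=Post-translational;T=Post-translational;Y=Post-translational
121	GG	114.042927	K=Post-translational;S=Post-translational;T=Post-translational;C=Post-translational
122	Formyl	27.994915	K=Artefact;S=Artefact;T=Artefact;N-term=Artefact
345	Trioxidation	47.984744	C=Post-translational;W=Artefact;Y=Artefact;F=Artefact
425	Dioxidation	31.989829	M=Artefact;W=Artefact;F=Artefact;Y=Artefact;C=Post-translational;P=Post-translational;K=Post-translational
530	Cation:K	37.955882	D=Artefact;E=Artefact;C-term=Artefact
951	Cation:Ca[II]	37.946941	D=Artefact;E=Artefact;C-term=Artefact
977	Carbofuran	57.021464	S=Chemical derivative
540	Ala->Ser	15.994915	A=AA substitution
544	Ala->Gln	57.021464	A=AA substitution
560	Gly->Asn	57.021464	G=AA substitution
567	Phe->Tyr	15.994915	F=AA substitution
1330	Glycyl	57.021464	K=Post-translational;S=Post-translational;T=Post-translational;C=Post-translational
1356	Pyrophospho	159.932661	S=Post-translational;T=Post-translational
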