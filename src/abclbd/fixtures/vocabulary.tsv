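cui	preferred_term	semantic_types	semantic_group
C0002395	alzheimer’s diseases	T047	DISO
C0003765	Arginine	T116,T123	CHEM
C0007222	Cardiovascular disease, NOS	T047	DISO
C0007745	Ceramides	T109,T121	CHEM
C0008405	Choline	T109,T121	CHEM
C0009450	Communicable disease, NOS	T047	DISO
C0010054	Arteriosclerosis, coronary	T047	DISO
C0011389	Dental plaques	T047	DISO
C0011860	Diabetes mellitus, non insulin dependent	T047	DISO
C0012634	Disease, NOS	T047	DISO
C0017770	Glucosylceramides	T109	CHEM
C0018790	Cardiac arrest	T047	DISO
C0019602	Histidine	T116,T123	CHEM
C0023401	Leucine	T116,T123	CHEM
C0024360	Lysophosphatidylcholines	T109	CHEM
C0025517	Metabolic disease, NOS	T047	DISO
C0026769	Multiple sclerosis, NOS	T047	DISO
C0028375	Norleucine	T116	CHEM
C0028754	Obesity, NOS	T047	DISO
C0031716	Phosphorylcholine	T109	CHEM
C0031951	Pipecolic acid	T109	CHEM
C0034341	Deficiency disease, pyruvate carboxylase	T047	DISO
C0036690	Septicaemia, NOS	T047	DISO
C0037906	Sphingomyelins	T109	CHEM
C0039082	Syndrome, NOS	T047	DISO
C0043194	Wiskott aldrich syndrome	T047	DISO
C0058624	Docosapentaenoic acid	T109	CHEM
C0069409	Oleoylcarnitine	T109	CHEM
C0070662	Phenylalanylphenylalanine	T116	CHEM
C0162429	Malnutrition NOS	T047	DISO
C0175697	Van der woude’s syndrome	T047	DISO
C0243026	Sepsis, NOS	T047	DISO
C0333262	Vesicle (morphologic abnormality)	T047	DISO
C0342895	Disease, fish-eye	T047	DISO
C0368608	Acylcarnitine	T109,T123	CHEM
C0556150	Docosahexaenoic acid	T109,T121	CHEM
C1720830	Painful bladder syndrome	T047	DISO
C2348307	Docosadienoic acid	T109	CHEM
C2348386	Eicosadienoic acid	T109	CHEM
C2348388	Eicosatrienoic acid	T109	CHEM
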