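species	scientific_name	accession	expected_length	source	complete
Human	Homo sapiens	NP_076985.4	1104	NCBI	True
Chimpanzee	Pan troglodytes	ENSPTRP00000022348	1052	Ensembl	True
Gorilla	Gorilla gorilla gorilla	ENSGGOP00000008197	1105	Ensembl	True
Orangutan	Pongo abelii	XP_002813060.1	1104	NCBI	True
Gibbon	Nomascus leucogenys	XP_003278601.1	1104	NCBI	True
Olive baboon	Papio anubis	ABX89284.1	1104	GenBank	True
Red-bellied titi	Callicebus moloch	ACA57875.1	1104	GenBank	True
Common marmoset	Callithrix jacchus	ABY79104.1	1104	GenBank	True
Bushbaby	Otolemur garnettii	ENSOGAP00000012043	1088	Ensembl	True
Dog	Canis lupus familiaris	NP_001104239.1	1104	NCBI	True
Panda	Ailuropoda melanoleuca	XP_002917995.1	1104	NCBI	True
Horse	Equus caballus	XP_001499536.1	1104	NCBI	True
Cow	Bos taurus	ENSBTAP00000019509	1104	Ensembl	True
Pig	Sus scrofa	XP_003133798.1	1104	NCBI	True
Squirrel	Spermophilus tridecemlineatus	ENSSTOP00000013235	1104	Ensembl	True
Guinea pig	Cavia porcellus	ACU30144.1	1104	GenBank	True
Rat	Rattus norvegicus	NP_599198.2	1104	NCBI	True
Mouse	Mus musculus	NP_599013.1	1104	NCBI	True
African elephant	Loxodonta africana	XP_003417951.1	1108	NCBI	True
Nine-banded armadillo	Dasypus novemcinctus	ACO88994.1	1104	GenBank	True
Tasmanian devil	Sarcophilus harrisii	ENSSHAP00000003620	1103	Ensembl	True
Zebra finch	Taeniopygia guttata	ENSTGUP00000003679	1087	Ensembl	True
Chicken	Gallus gallus	ENSGALP00000039026	1106	Ensembl	True
Xenopus	Xenopus laevis	NP_001155066.1	1139	NCBI	True
Wallaby	Macropus eugenii	ENSMEUP00000004623	1050	Ensembl	False
Turkey	Meleagris gallopavo	ENSMGAP00000002375	1069	Ensembl	False
Tree shrew	Tupaia belangeri	ENSTBEP00000008744	1104	Ensembl	False
Tarsier	Tarsius syrichta	ENSTSYP00000009832	1064	Ensembl	False
Sloth	Choloepus hoffmanni	ENSCHOP00000006168	1048	Ensembl	False
Platypus	Ornithorhynchus anatinus	ENSOANP00000020169	1096	Ensembl	False
Pika	Ochotona princeps	ENSOPRP00000001346	1103	Ensembl	False
Opossum	Monodelphis domestica	ENSMODP00000010005	1096	Ensembl	False
Mouse lemur	Microcebus murinus	ENSMICP00000013415	1090	Ensembl	False
Megabat	Pteropus vampyrus	ENSPVAP00000005934	1092	Ensembl	False
Macaque	Macaca mulatta	ENSMMUP00000027950	192	Ensembl	False
Dolphin	Tursiops truncatus	ENSTTRP00000004154	1103	Ensembl	False
Coelacanth	Latimeria chalumnae	ENSLACP00000016045	1044	Ensembl	False
Anole lizard	Anolis carolinensis	ENSACAP00000010017	1103	Ensembl	False
Alpaca	Vicugna pacos	ENSVPAP00000002122	1059	Ensembl	False
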