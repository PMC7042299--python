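# Per-family known-locus triage fixture: gene and best pathogenicity
# category at an established locus, one row per reported variant.
# Families with no known-locus finding enter the WES discovery arm.
family_id	gene	tier	category
FML001	RUNX1	high	pathogenic
FML002	RUNX1	high	pathogenic
FML003	RUNX1	high	pathogenic
FML004	RUNX1	high	pathogenic
FML005	RUNX1	high	pathogenic
FML006	RUNX1	high	pathogenic
FML008	CEBPA	high	pathogenic
FML009	CEBPA	high	pathogenic
FML010	CEBPA	high	pathogenic
FML011	CEBPA	high	pathogenic
FML015	GATA2	high	pathogenic
FML016	GATA2	high	pathogenic
FML017	GATA2	high	pathogenic
FML020	DDX41	high	pathogenic
FML021	DDX41	high	pathogenic
FML022	DDX41	high	pathogenic
FML023	TERT	high	pathogenic
FML024	TERT	high	pathogenic
FML025	TERT	high	pathogenic
FML026	TERT	high	pathogenic
FML027	TERC	high	pathogenic
FML028	TERC	high	pathogenic
FML033	ANKRD26	high	pathogenic
FML034	ANKRD26	high	pathogenic
FML035	ETV6	high	pathogenic
FML036	TP53	high	pathogenic
FML046	GATA2	high	pathogenic
FML038	SRP72	moderate	pathogenic
FML039	ACD	moderate	pathogenic
FML040	SAMD9	moderate	pathogenic
FML042	ERCC6L2	emerging	pathogenic
FML043	ATG2B/GSKIP	emerging	pathogenic
FML007	CEBPA	high	pathogenic
FML012	DDX41	high	likely_pathogenic
FML013	DDX41	high	likely_pathogenic
FML014	ETV6	high	VUS
FML018	GATA2	high	pathogenic
FML019	GATA2	high	likely_pathogenic
FML029	RUNX1	high	likely_pathogenic
FML030	RUNX1	high	likely_pathogenic
FML031	RUNX1	high	likely_pathogenic
FML032	SAMD9L	moderate	VUS
FML037	TERC	high	likely_pathogenic
FML041	TERT	high	pathogenic
FML044	FANCA	emerging	pathogenic
FML044	FANCA	emerging	VUS
FML045	MECOM	emerging	likely_pathogenic
FML047	SBDS	emerging	pathogenic
FML047	SBDS	emerging	pathogenic
FML048	WAS	emerging	likely_pathogenic
FML049	TP53	high	likely_pathogenic
FML050			none
FML051			none
FML052			none
FML053			none
FML054			none
FML055			none
FML056			none
FML057			none
FML058			none
FML059			none
FML060			none
FML061			none
FML062			none
FML063			none
FML064			none
FML065			none
FML066			none
FML067			none
FML068			none
FML069			none
FML070			none
FML071			none
FML072			none
FML073			none
FML074			none
FML075			none
FML076			none
FML077			none
FML078			none
FML079			none
FML080			none
FML081			none
FML082			none
FML083			none
FML084			none
FML085			none
FML086			none
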