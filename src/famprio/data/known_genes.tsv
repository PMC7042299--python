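# Established MDS/AML predisposition loci with evidence tier and inheritance model.
# Tiers: high / moderate evidence for gene-disease association, or emerging
# (basic research / other inherited hematological syndromes with high MDS/AML risk).
gene	tier	inheritance
ANKRD26	high	AD_het
CEBPA	high	AD_het
DDX41	high	AD_het
ETV6	high	AD_het
GATA2	high	AD_het
RUNX1	high	AD_het
TERC	high	AD_het
TERT	high	AD_het
TP53	high	AD_het
ACD	moderate	AD_het
CHEK2	moderate	AD_het
RTEL1	moderate	AD_het
SAMD9	moderate	AD_het
SAMD9L	moderate	AD_het
SRP72	moderate	AD_het
ATG2B/GSKIP	emerging	AD_het
ERCC6L2	emerging	AR_biallelic
FANCA	emerging	AR_biallelic
MBD4	emerging	AD_het
MECOM	emerging	AD_het
SBDS	emerging	AR_biallelic
WAS	emerging	XL_hemizygous
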