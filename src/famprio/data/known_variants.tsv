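# Established familial MDS/AML variants used as the previously-described lookup.
gene	hgvs_c	hgvs_p
CEBPA	c.985_988dupGAAC	p.Gln330Argfs*74
DDX41	c.3G>A	p.Met1?
DDX41	c.370C>T	p.Arg124X
GATA2	c.1061C>T	p.Thr354Met
GATA2	c.1084C>T	p.Arg362X
SAMD9L	c.4418G>A	p.Ser1473Asn
TERT	c.1445delA	p.His482Profs*27
FANCA	c.2505-1G>T	
SBDS	c.258+2T>C	
SBDS	c.183_184delinsCT	p.Lys62X
WAS	c.1336delA	p.Lys446fs
TP53	c.844C>T	p.Arg282Trp
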