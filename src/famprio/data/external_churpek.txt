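# Candidate familial MDS/AML loci from a prior WES family series (Churpek and
# colleagues); reduced to the overlap named in print.
DNAH9
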