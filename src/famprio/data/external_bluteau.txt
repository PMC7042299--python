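# Causal / likely causal / possibly contributing genes from a large inherited
# bone-marrow-failure cohort (Bluteau and colleagues); reduced to the overlaps
# named in print.
SH2B3
PRF1
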