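# Constitutional RUNX1 deletions in the three familial-platelet-disorder families.
# Coordinates are 1-based inclusive as printed; FML031 has two published
# breakpoint pairs (tabulated vs narrative) and both are retained. The
# tabulated set is the default for the common-segment computation.
family	chrom	start	end	source
FML029	chr21	36349450	36572837	table
FML030	chr21	36400658	36972948	table
FML031	chr21	36389492	37056053	table
FML031	chr21	36389457	37055677	text
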