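# SYNTHETIC illustrative RUNX1 feature model (distal promoter and first exons
# of the minus-strand gene). Coordinates are stand-ins chosen so that the
# distal promoter and exons 1-2 fall inside the constitutional-deletion
# common segment; they are NOT curated annotation.
name	chrom	start	end
exon3	chr21	36260000	36261000
exon2	chr21	36420000	36421500
exon1	chr21	36520000	36521000
distal_promoter	chr21	36570000	36572500
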