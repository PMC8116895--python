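# Default celiac-disease epitope table for the alpha-gliadin amplicon region.
# Peptide strings are literature-derived immunology reference sequences
# (DQ2.5-restricted 9-mer cores and the two major p31-43 innate-peptide forms);
# they are configuration data and can be overridden with a custom TSV.
# Categories: 33mer_constituent (the three epitopes whose overlapping copies
# form the 33-mer), flanking_dq2 (DQ2.5 epitope flanking the 33-mer),
# innate_peptide (non-T-cell innate response peptide; does not count toward
# CD-epitope status).
name	peptide	category
DQ2.5-glia-a1a	PFPQPQLPY	33mer_constituent
DQ2.5-glia-a1b	PYPQPQLPY	33mer_constituent
DQ2.5-glia-a2	PQPQLPYPQ	33mer_constituent
DQ2.5-glia-a3	FRPQQPYPQ	flanking_dq2
p31-43-LG	LGQQQPFPPQQPY	innate_peptide
p31-43-LP	LPQQQPFPPQQPY	innate_peptide
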