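# Default gene exclusion list for define_gene_set: the uracil biosynthesis
# pathway, whose expression is perturbed by the URA3 marker cassette used to
# construct the knockouts rather than by the deleted TF itself.
# Edit or replace to suit a different marker system.
excluded_genes:
  - URA1
  - URA2
  - URA3
  - URA4
  - URA5
  - URA6
  - URA7
  - URA8
  - URA10
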