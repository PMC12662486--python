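# Demo study: fully simulated microbiota -> metabolite -> disease screen.
# One causal taxon (taxon_00) acting on the disease partly through one true
# mediator (metabolite_00); all other taxa/metabolites are null.
seed: 20260927
alpha: 0.05
suppression_rule: footnote
n_boot: 200
n_sim: 500
simulation:
  n_taxa: 6
  n_metabolites: 5
  n_disease_snps: 40
  base:
    n_snps: 50
    a_true: 0.3
    b_true: 0.2
    c_prime_true: 0.1
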