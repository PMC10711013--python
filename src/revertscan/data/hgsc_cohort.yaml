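# Published post-PARPi HGSC study cohort: headline counts used for
# prevalence arithmetic and worked examples.
n_patients: 26
n_brca_mutant: 21          # germline or somatic BRCA1/2, reversion-eligible
n_reversion_patients: 3
n_pre_parpi_available: 13
hr_mutations:
  germline_BRCA1: 13
  germline_BRCA2: 4
  somatic_BRCA1: 2
  somatic_BRCA2: 1
  unknown_BRCA1: 1
  wildtype: 5
tp53_median_vaf: 0.63
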