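# Example data

`crp_cad_etable_a1.csv` (not distributed here): the published table of 17
genetic variants associated with C-reactive protein (CRP) at genome-wide
significance, with per-allele associations with log-transformed CRP
concentrations and per-allele log odds ratios for coronary artery disease
(CAD) from the CARDIoGRAM consortium.  This package does not redistribute
those association estimates; to run the CRP–CAD worked example, obtain
the table from its public supplement and save it here with the canonical
header:

```
variant,beta_exposure,se_exposure,beta_outcome,se_outcome
```

(one row per variant; `beta_exposure`/`se_exposure` on log CRP,
`beta_outcome`/`se_outcome` on log odds of CAD).  The worked-example test
in `tests/test_acceptance.py` and the corresponding block of
`scripts/acceptance.py` pick the file up automatically.
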