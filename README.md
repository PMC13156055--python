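# pvsignal

Disproportionality analysis of spontaneous adverse-event reports, with
rank correlation of signal strength against receptor binding-affinity
profiles.

Spontaneous-reporting databases (FAERS-style DEMO/DRUG/REAC tables)
collect voluntary reports of suspected adverse drug reactions. Because
they have no denominator, drug–event associations are screened by
*disproportionality*: for a drug D and an event set E, the deduplicated
report universe is partitioned into a 2×2 table

|            | event in E | other events |
|------------|-----------|--------------|
| D primary suspect | a | b |
| other drugs       | c | d |

and four statistics are computed with their conventional signal
thresholds:

- **ROR** = ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  signal if N ≥ 3 and ROR₀₂₅ > 1.
- **PRR** = [a/(a+b)] / [c/(c+d)] with the uncorrected Pearson χ²;
  signal if PRR ≥ 2, χ² ≥ 4, N ≥ 3.
- **IC** (BCPNN information component) = log₂((a+0.5)/(aexp+0.5)) with
  aexp = (a+b)(a+c)/n and IC₀₂₅ = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2);
  signal if IC₀₂₅ > 0.
- **EBGM**, here the observed/expected relative reporting ratio a/aexp
  with log-normal interval bounds (no gamma-Poisson shrinkage; see
  `docs/methods.md`); signal if EBGM₀₅ > 2.

The package provides the full desk-scale workflow around these
statistics: a synthetic report generator with planted, analytically
tractable drug–event associations; ingest (drug-name normalization,
case-version deduplication, primary-suspect filtering); a minimal
MedDRA-style PT→HLT→HLGT→SOC hierarchy with a packaged seizure fixture;
the screening engine; demographic summaries; and Spearman correlation
of group-level signal strength against receptor Ki profiles (six
monoamine receptors and three serotonin/D2 Ki ratios), with exact
permutation p-values at small n. It is aimed at pharmacovigilance
methodologists who want a tested, reproducible reference implementation
rather than spreadsheet arithmetic.

## Worked example

Run the shipped demonstration pipeline (20,000 synthetic reports,
twelve drugs, planted seizure signals):

```sh
pvsignal run-all -o out/
```

`out/signals.tsv` contains one row per (drug, PT) pair with ≥ 3 cases
plus one group-level row per drug. The planted strong pair —
quetiapine × Status epilepticus, planted with an 8-fold event-rate
multiplier — comes out as (rounded to 2 dp):

```
a=60  ROR=9.60 (6.93–13.29)  PRR=9.18  chi2=275.54
IC=2.55 (IC025=2.12)  EBGM=6.11 (EBGM05=4.41)   all four flags raised
```

i.e. quetiapine-suspect reports mention status epilepticus about nine
times more often than the rest of the universe, and the association
clears every threshold, Bayesian bounds included.

Correlating the packaged reference signal values against the packaged
receptor Ki panel:

```sh
pvsignal correlate -o out/
```

```
   column  n       rho  p_two_sided            method
       D1  6  0.200000     0.713889 exact_permutation
       D2  7  0.821429     0.034127 exact_permutation
      ...
5-HT1A/D2  7 -0.892857     0.012302 exact_permutation
```

Here each drug's group-level ROR₀₂₅ is rank-correlated against its
mean Ki per receptor (pairwise-complete per column, hence the varying
n); a strong negative rho for Ki(5-HT1A)/Ki(D2) means drugs whose
5-HT1A binding is weak relative to their D2 binding carry the larger
seizure signals. (The table above is for the synthetic demo ROR values;
the curated reference ROR column gives rho = −0.79 for that ratio.)

Other subcommands: `pvsignal generate` (emit raw demo/drug/reac
tables), `pvsignal screen` (clean + screen existing tables). All accept
a YAML configuration; the packaged default is
`src/pvsignal/data/demo_config.yaml`.

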