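# Methods

## Report universe and counting unit

The unit of analysis is the deduplicated report: one row per case
identifier, retained as the version with the numerically greatest
report identifier ("latest version wins" — deterministic and
order-independent; real reporting systems key duplicate resolution on
the case identifier, sometimes with dates, which spontaneous extracts
do not always carry). A report contributes at most once to cell *a*
for a given drug–event pair even if it lists the event term twice, and
group-level (HLGT) counts are unique-report counts over the union of
member PTs, not sums of PT-level counts. Only drugs in the
primary-suspect (PS) role define exposure; secondary-suspect,
interacting, and concomitant mentions never enter a contingency table.

## Contingency convention and statistics

Cells are labelled a = drug∧event, b = drug∧¬event, c = ¬drug∧event,
d = ¬drug∧¬event. Under this convention the four statistics are the
standard ones: ROR = ad/bc, PRR = [a/(a+b)]/[c/(c+d)],
aexp = (a+b)(a+c)/n, IC = log₂((a+0.5)/(aexp+0.5)), EBGM = a/aexp.
PRR ≈ ROR whenever the event is rare in both exposure arms, which is
the operating regime of spontaneous-report screens and a useful
cross-check between the two.

Numerical choices:

- χ² is the uncorrected Pearson statistic (no Yates correction).
- No Haldane 0.5 correction anywhere: a statistic whose formula needs a
  positive cell that is zero is reported as NaN ("undefined") and its
  flag is false. With the N ≥ 3 screen, a = 0 is moot; b = 0 or c = 0
  can occur on small universes and must not crash.
- **EBGM is implemented exactly as the observed/expected relative
  reporting ratio a/aexp with log-normal bounds using the same
  log-scale SE as the ROR.** This is deliberately *not* the multi-item
  gamma-Poisson shrinker: no prior mixture is fitted. At large a the
  two coincide; at small a the true MGPS shrinks harder. Users wanting
  shrinkage at small counts should rely on IC₀₂₅, whose penalty term
  3.3(a+0.5)^(−1/2) + 2(a+0.5)^(−3/2) supplies it explicitly.
- Threshold comparisons on interval bounds are strict (IC₀₂₅ > 0,
  EBGM₀₅ > 2, ROR₀₂₅ > 1); PRR ≥ 2, χ² ≥ 4 and N ≥ 3 are inclusive,
  as conventionally printed.
- Internal values are kept at full precision; display rounding is
  2 dp, half away from zero.

Monotonicity caveat: all four statistics grow strictly in a (holding
b, c, d) only while a stays below its co-margins; EBGM = a·n/((a+b)(a+c))
behaves like n/a for a far beyond them. The property suite tests the
signal-detection regime a < b, c.

## Term hierarchy

A minimal PT→HLT→HLGT→SOC table stands in for the licensed MedDRA
distribution. The packaged seizure fixture holds 25 PTs under the HLGT
"Seizures (incl subtypes)" with plausible HLT groupings; it is
necessarily incomplete relative to the full dictionary (the real HLGT
has more members), so group-level counts on real data filtered through
it would be undercounts. Both the "Hyponatraemic seizure" and
"Hyponatremic seizure" spellings occur in circulating data and are kept
as distinct entries, linked by `PT_ALIASES`. PT matching is exact and
case-sensitive after a single strip at load: fuzzy matching of a
controlled vocabulary invites silent errors.

## Synthetic report generator

The generator emulates the structure the pipeline consumes, not the
epidemiology behind it. Each report draws one PS drug from a marginal
distribution; each catalog PT is then an independent Bernoulli with
probability p·λ(drug, PT), where the rate multiplier λ (default 1)
plants associations. Independence across PTs is what makes every 2×2
cell available in closed form (`expected_contingency`), which is the
point of the generator. Demographics are age ~ N(42, 18²) clipped to
[1, 95], balanced sex, a six-country mix (US weight 0.5), each with
configurable missingness. Duplicate case versions are emitted after
all originals with larger report identifiers and completed
demographics; a synonym-bearing raw drug spelling exercises the
normalizer.

Two deliberate approximations:

- **Zero-event redraw.** Reports with no event are redrawn, so every
  report mentions ≥ 1 PT (REAC semantics). This conditions the event
  vector on ≥ 1 event and inflates every per-PT rate by roughly
  1/P(≥ 1 event). `expected_contingency` ignores the redraw; its
  closed forms are accurate when background PTs give reports a high
  chance of at least one event, and the Monte-Carlo tests check both
  the exact conditional expectation and the closeness of the
  unconditioned approximation. Odds *ratios* are nearly preserved by
  the conditioning (both arms inflate similarly), which is why planted
  odds ratios are recovered even where single cells drift.
- **λ multiplies the event probability, not its odds.** The analytic
  odds ratio induced by λ at background rate p is therefore slightly
  above λ; `multiplier_for_odds_ratio(target_or, p)` inverts the
  relation when a specific odds ratio must be planted (used by the
  planted-OR-13 recovery test).

What the generator does *not* model: reporting-date dynamics, dose,
indication, correlated event co-occurrence (real syndromes co-report),
drug-specific reporting propensities, or notoriety bias. Passing tests
therefore demonstrate correctness of the counting and statistics
machinery under a known model — not that real-data signals are
unbiased, which disproportionality never guarantees.

Shipped demonstration conditions (`demo_config.yaml`): 20,000 reports,
eight antipsychotics (marginals 3–6%) over four high-volume background
drugs, five seizure PTs (background rates 0.1–1.2%) among seven common
background PTs, planted multipliers 1.5–4.5 mirroring the qualitative
hierarchy seen in public reporting data, one strong pair (8×) sized to
clear all four thresholds at this n, 5% duplicates, and missingness of
25% (age), 8% (sex), 5% (country). Test and acceptance runs use
20,000–200,000 reports; these sizes give the binomial 3σ checks real
power while keeping the whole suite fast.

## Receptor correlation

Per-drug receptor affinity is the arithmetic mean of curated Ki values
(nM); the packaged table carries the eight atypical antipsychotics and
six receptors (D1, D2, D3, 5-HT1A, 5-HT2A, 5-HT2C), with missing
entries where no curated value exists. Ratios Ki(5-HTx)/Ki(D2) are
derived, inheriting missingness from either parent. Signal strength is
the group-level ROR₀₂₅.

- **Scale choice.** Correlations default to the raw Ki scale (and raw
  Ki ratios) because that is how such panels are printed and signed;
  the reciprocal 1/Ki "affinity index" (larger = stronger binding) is
  exposed via `use_inverse_affinity=True` and, being a monotone
  reversal, exactly flips every Spearman sign. Describing results as
  "affinity" correlations while computing on the Ki scale is a common
  source of sign confusion; exposing both modes makes the choice
  explicit.
- **Missing data** are handled pairwise-complete per column, so n
  varies by column (listwise deletion would force every column down to
  the complete-case drugs and cannot reproduce per-column n of 6, 7
  and 8 from the same eight-drug table).
- **p-values.** Ties get mid-ranks; rho uses the Σd² identity when
  tie-free, Pearson-on-ranks otherwise. For n ≤ 9 the two-sided p is
  exact: the fraction of all n! rank permutations with
  |rho| ≥ |rho_obs| − 10⁻¹², the tolerance guarding float equality at
  the observed statistic. Beyond n = 9, t = rho·√((n−2)/(1−rho²)) on
  n − 2 df. The two differ materially at panel-sized n: for the
  strongest ratio column of the reference panel (n = 7,
  rho = −0.7857), exact enumeration gives p = 242/5040 ≈ 0.048 while
  the t approximation — the default of SPSS-style packages, and the
  value such analyses usually print — gives 0.036. The package reports
  whichever method was used alongside the p-value so the two are never
  conflated.

## Pipeline

`run-all` chains generate → write/reload raw tables → normalize →
deduplicate → hierarchy filter → screen → demographics → correlate,
writing TSV/JSON outputs plus a manifest (seed, version, provenance
counts). All randomness flows from the single generator seed and no
output embeds a timestamp, so a rerun is byte-identical. Demographic
tables (age bins ≤ 18 / 19–59 / ≥ 60 / unknown, sex, US vs non-US)
are computed on each drug's *signal-positive* cases — reports backing
PT-level pairs that pass the ROR criterion — matching how such
population tables are typically scoped; row-count provenance
(raw = retained + no-event + duplicates) reconciles at every stage.

## Known limitations

- The EBGM column is an unshrunk observed/expected ratio (above); its
  lower bound at very small a is anti-conservative relative to a true
  MGPS fit.
- The seizure hierarchy fixture is a subset of the real HLGT
  membership.
- Exact permutation p-values are capped at n = 9 (9! enumerations);
  larger panels silently use the t approximation (reported in the
  `method` field).
- The generator's per-PT independence cannot express syndrome-level
  co-reporting, so it cannot be used to study correlated-event
  artefacts.
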