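# Methods

## Report cleaning

FAERS-style quarterly extracts are `$`-delimited with one DEMO row per
report version, one DRUG row per drug mention (role codes PS/SS/C/I) and
one REAC row per reaction preferred term. Cleaning applies, in order:

1. **Primary-suspect restriction** — only cases where a target drug is the
   primary suspect (PS). Matching is case-insensitive exact match on
   whitespace-normalized names against a user-supplied list of generic and
   brand names (substring mode optional); name lists are configuration, not
   code.
2. **Reporter restriction** — only healthcare-practitioner occupation codes
   (MD, HP, PH, RN, OT); missing codes are removed.
3. **Deduplication** — one record per CASEID: the latest FDA_DT wins, date
   ties go to the higher PRIMARYID (numeric comparison when every version's
   id is numeric, lexicographic otherwise), and a missing date loses every
   comparison.

Provenance counts are recorded per step in this order; applying the steps
in another order changes the per-step counts but not the final case set
when a case's versions agree on drug and reporter, which is the duplicate
pattern deduplication targets. Cases with no REAC rows are kept with an
empty PT set and flagged — dropping them would shrink the denominators b
and d and inflate every disproportionality statistic.

Dates stay integer YYYYMMDD; anything that is not an 8-digit valid calendar
date becomes missing and is counted in the parse warnings.

## Event dictionary

The bundled dictionary holds the narrow-scope renal SMQs (21
acute-kidney-injury PTs, 43 chronic-kidney-disease PTs; six procedure/
azotemia/renal-failure terms belong to both, so the distinct union is 58)
plus a deliberately minimal renal/urinary SOC demo list of five PTs.
The full SOC list (several hundred PTs in current MedDRA) is licensed
vocabulary and must be supplied by the user; the SOC fallback warns rather
than silently returning nothing when it is absent. Matching is exact after
trim/whitespace-collapse/casefold — reaction strings in cleaned reports are
already MedDRA PTs, and fuzzy matching would manufacture signals. Near
misses at edit distance 1 are logged for manual review only.

## Disproportionality statistics

All four statistics derive from the case-level 2×2 table; a case counts
once per cell regardless of how many of its PTs fall in the event group.
The background comparator for a drug is every other cleaned case in the
same snapshot (the drug's own reporting window), so N = a+b+c+d is the
snapshot size for every pair.

- ROR = ad/bc, 95% CI = exp(ln ROR ± 1.96·s), s² = 1/a+1/b+1/c+1/d.
- PRR = a(c+d)/(c(a+b)); χ² is the Pearson statistic
  (ad−bc)²N/((a+b)(c+d)(a+c)(b+d)) with no continuity correction.
- IC = log₂(aN/((a+c)(a+b))); IC025 = IC − 2√V with V = s²/ln(2)² — the
  delta-method variance of the log₂ relative reporting ratio.
- EBGM = aN/((a+c)(a+b)) = 2^IC, the observed/expected relative reporting
  ratio; EBGM05 = exp(ln EBGM − z·s).

Conventions that needed a decision:

- **EBGM05 uses z = 1.64** (configurable). The FAERS-mining literature is
  split between 1.64, 1.645 and 1.96 for the "EBGM05" lower bound;
  z = 1.64 is the convention under which this package's worked-example
  values reproduce published four-algorithm tables digit-for-digit, so it
  is the default.
- **EBGM here is the closed-form relative reporting ratio**, not the
  shrunken posterior mean of DuMouchel's gamma-mixture MGPS. With counts in
  the ranges screened here (a ≥ 3 against multi-million backgrounds) the
  shrinkage correction is small; fitting the full empirical-Bayes mixture
  is out of scope and would add a model-fitting failure mode to a
  screening statistic.
- **IC025 uses the count-based formula above.** Published tables sometimes
  print IC − IC025 gaps that are constant across rows and cannot come from
  any count-dependent variance; no alternative formula is guessed. For
  a = 3 rows the count-based bound coincides with such published values
  (the 1/a term dominates); for larger a it is tighter.
- **No multiplicity adjustment** across events: thresholds are applied per
  pair, as is standard for hypothesis-generating spontaneous-report
  screens. The conservatism comes from requiring all four algorithms to
  fire (configurable to "any").
- Undefined statistics (zero cells/margins) are reported as NaN with an
  explicit reason and never fire a criterion; a pair needs a ≥ 3 to be
  evaluable at all.
- Display rounding is half-up to 2 decimals; internal values keep full
  precision.

Screening evaluates every PT observed for the drug plus the pooled AKI and
CKD SMQ PT sets (both per-PT and pooled views are useful; the pooled rows
are labeled "(SMQ narrow)"). Output is sorted positives-first by descending
ROR. Forest export writes the tidy decision table and, optionally, a
log-scale ROR/CI forest plot. Demographic summaries band age as <18,
18–59, 60–69, 70–79, ≥80 years (converting FAERS age-unit codes) and
weight as <40, 40–59, 60–79, 80–99, ≥100 kg, tallying missing values
separately.

## Mendelian randomization

Instruments for a drug-target protein are cis-pQTLs passing four filters:
position within `cis_window_bp` (default 500,000) of the coding region
(1-based inclusive, both flanks), P < 5×10⁻⁸, greedy LD clumping at
r² < 0.001 within a 10 Mb window (most significant first, rsID tie-break;
a missing LD entry is fatal rather than assumed independent), and
single-variant F = (β/se)² > 10. The F form is the standard single-SNP
instrument-strength statistic.

Harmonization aligns outcome effects to the exposure's effect allele,
flipping the outcome beta for reversed (or reversed-complement) allele
labels. Palindromic variants (A/T, C/G) are dropped when either study's
effect-allele frequency lies in [0.42, 0.58] and otherwise resolved by
frequency.

The **positive-control gate** encodes the design principle that instruments
must first reproduce a known effect: the harmonized instruments are run
against a control outcome (for a therapeutic target, the treated disease),
and only a nominally significant control estimate (p < 0.05) with the
configured expected direction lets the pipeline estimate the primary (and
optional replication) outcome. Otherwise the report carries status
`instruments_not_validated` (or `no_instruments`) and no primary estimate.

Estimators, on per-variant Wald ratios θᵢ = β_out,i/β_exp,i with
first-order SEs se_out,i/|β_exp,i| (a second-order SE including exposure
uncertainty is available behind a flag):

- **Wald ratio** for a single instrument.
- **IVW**: fixed-effect pooling with weights 1/se(θᵢ)².
- **MR-Egger**: WLS of β_out on β_exp with intercept, weights 1/se_out²,
  exposure betas oriented positive; the slope is the estimate, the
  intercept (t-test, n−2 df) is the directional-pleiotropy test. Constant
  exposure betas are refused as unidentifiable.
- **Weighted median**: interpolated 50th weighted percentile of the ratios;
  SE by parametric bootstrap (1,000 seeded draws).
- **Simple/weighted mode**: mode of the normal-kernel-smoothed ratio
  density, bandwidth φ·0.9·min(sd, MAD)·n^(−1/5) with φ = 1; SE by
  parametric bootstrap.
- **Cochran's Q** around the IVW estimate (χ², n−1 df) for heterogeneity.

Odds ratios are exp(β) with 95% CI exp(β ± 1.96·se). No multiple-testing
correction is applied across outcomes; interpretation is at nominal p.

## Synthetic data

The FAERS generator draws each logical case as one report: a suspect drug
(uniform over a background drug vocabulary, plus a fixed number of
target-drug reports), one reaction PT from the drug's multinomial PT
distribution, and demographic strata (occupation mix including
non-practitioner codes, sex, age bands, weight, quarter). A planted signal
(drug, PT, ρ) multiplies that PT's probability by ρ within the drug and
renormalizes. A configured fraction of cases is emitted twice under the
same CASEID — half with a later FDA_DT, half same-date with a higher
PRIMARYID — so both deduplication rules are exercised. Defaults (50,000
background reports over 20 drugs, 2,000 target reports, background renal-PT
rates 0.2–0.5%, 5% duplicates, ~85% practitioner reporters) give planted
ρ = 5 signals expected cell counts around a ≈ 40 against c ≈ 250 —
comfortably detectable, yet small enough that a hundred seeded snapshots
run in minutes. The manifest records the exact per-drug PT probabilities
and the analytically expected post-cleaning cell counts, so any pipeline
count can be checked against closed form.

What the generator does **not** emulate: multi-drug polypharmacy reports,
correlated PT co-reporting, reporting-rate drift over quarters, real
marginal PT frequencies, or free-text drug-name noise. Passing calibration
therefore shows the statistics and plumbing are correct under a clean
multinomial reporting model, not that real FAERS extracts are free of
those complications.

The GWAS generator works at the summary level: SNPs sit in block-diagonal
LD blocks (configurable block size and within-block r²), lead SNPs of the
first `n_instruments` blocks carry true exposure effects around
`instrument_beta` (random sign, ±25% magnitude), tagged neighbors inherit
the r-attenuated effect, and observed betas are truth plus independent
N(0, se) noise for exposure, control and outcome (β_out = θ·β_true + δ).
Defaults (β ≈ 0.15, se ≈ 0.01, hence F ≈ 225) emulate a strong
protein-level cis signal at proteomics-biobank scale. Because the noise is
independent across the three tables, the two-sample assumption holds by
construction.

## Calibration studies

`pvmr.calibration` runs the operating-characteristic studies the test
suite and the acceptance script report:

- **Screen null calibration** — 100 seeded snapshots with no planted
  signal; the fraction of evaluated drug-event pairs flagged by all four
  algorithms is the empirical false-positive rate (observed well below the
  5% bound; requiring four criteria simultaneously is conservative).
- **Screen power** — 100 seeded snapshots with a planted ρ = 5 signal;
  detection is the planted pair itself coming out positive.
- **MR recovery** — seeded simulations at θ ∈ {−0.3, 0, 0.3} for the Wald
  ratio (1 instrument) and IVW (10 instruments): mean bias, empirical 95%
  CI coverage, and type-I error at θ = 0 over 1,000 simulations. Recovery
  uses mutually independent instruments so it measures the estimators, not
  instrument selection: selecting the most significant SNP among
  correlated block-mates adds a winner's-curse attenuation (~5% of θ under
  the default noise levels) that is a known property of any
  select-then-estimate workflow and is documented rather than hidden.

## Known limitations

- The relative reporting ratio EBGM (hence IC) is not monotone in a at
  very small counts — increasing a also inflates both margins — so "more
  target-event cases" does not always mean "larger EBGM" near a ≤ 3.
- The SOC fallback is only as complete as the user-supplied SOC PT list;
  the bundled five-term demo list exists for exercising the code path.
- Egger's slope is weakly identified when instrument strengths are nearly
  constant (its design matrix approaches collinearity); the implementation
  refuses the exactly-constant case and otherwise reports honest (large)
  SEs.
- LD clumping consumes a user-supplied pairwise r² matrix; there is no
  reference-panel genotype processing.
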