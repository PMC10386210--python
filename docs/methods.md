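# Methods

This note documents the statistical procedures, the synthetic world the
package is validated against, and the numerical and design choices a
maintainer would want to know. Nothing here states an empirical result
that the test suite or the analysis scripts do not themselves compute.

## The disproportionality model

A spontaneous reporting system (SRS) is a case series, not a cohort:
there is no denominator of drug users, so incidence cannot be estimated.
What can be estimated is *disproportionality* — whether an event is
reported more often with a drug than the rest of the database would
predict. For each (drug, event-set) pair, unique cases are cross-tallied
into a 2×2 table (a = with drug and event, b = with drug only, c = event
only, d = neither; a+b+c+d = number of analysis cases) and the reporting
odds ratio ROR = ad/bc is computed.

**Haldane correction.** 0.5 is added to every cell before computing the
ROR and its CI. This keeps the ratio defined for zero cells and reduces
small-sample bias of the log odds ratio. The correction is *not* applied
to the Fisher exact test, which runs on the raw counts — the exact test
needs no continuity repair, and correcting its counts would change its
null distribution.

**Confidence interval.** The log-scale Wald (Woolf) interval on the
corrected cells with z = 1.959964. The variance estimate is
Σ 1/(cell+½). This is the standard pharmacovigilance construction; no
exact or profile-likelihood interval is attempted.

**Fisher exact test, two-sided.** The minimum-likelihood convention: the
p-value sums the hypergeometric point probabilities, over all tables with
the observed margins, that do not exceed the observed table's. This is
the convention of `scipy.stats.fisher_exact` and most statistical
software; other two-sided definitions (doubling the one-sided p, central
intervals) can differ in the third decimal. The implementation delegates
to scipy; the test suite checks it against an independent exact-rational
full-enumeration oracle on every table with margins ≤ 12.

**Signal criterion.** ROR ≥ 1 and p < 0.05, with no multiple-testing
adjustment — the convention of the published screen this package
reproduces. A Benjamini–Hochberg variant is available (`--fdr` /
`apply_fdr`) but off by default, because changing the criterion would
change what "signal" means relative to the reference numbers.

**Counting unit.** Every statistic counts unique case identifiers, never
record rows. The flow log records both scales so a record-level database
size can still be reconciled.

## ETL of the JADER dialect

The canonical dialect is UTF-8 comma-separated CSV with a header row
(real JADER exports are Shift-JIS; readers take `encoding=`). The
construction procedure is: (1) stack ";"-merged multi-value fields into
one row per atomic value (DRUG: drug name, route, date, dose, dose unit,
divided doses; DEMO: reporter) and split combination-drug names on the
"·" interpunct; (2) drop exact-duplicate rows within each table —
"duplicate" is defined as a byte-identical row after stacking, the only
operational definition available; (3) inner-join on the case id (an
analysable case needs demographics, at least one drug record and at least
one reaction record); (4) drop every case exposed to an indicator
medication (configured list, e.g. glaucoma eye drops marking prevalent
disease). Drug and PT names are normalised by trimming, case-folding and
an optional synonym map; matching is exact string equality afterwards.

The drug-name field is also split on ";" (not only "·"): merged
multi-drug rows occur in the wild and the cleaning stage must be
insensitive to them (see "mess neutrality" below). Sequential per-field
stacking expands a row with two merged fields to their cartesian product;
this is harmless because downstream analysis consumes case-level *sets*.

**Age tokens.** JADER codes age in decades ("20s" … "90s") with coarse
categories ("elderly", "adult", "unknown") and missing values. For the
age comparisons, "elderly" (an unspecified 70+ category) is mapped into
the ≥70 and ≥40 groups; "adult" and "unknown" carry no decade information
and are excluded per factor; the under-10 decade sits below both cut
points. Exclusions are per factor, so a case missing sex still
contributes to the age factors.

## Structure analysis

Per-term resolution uses one Haldane lnROR per (drug, single PT) pair,
with the full analysis table as denominator — the same 2×2 scheme as the
screen, with the event set shrunk to one PT. The published screen never
states this denominator; using all analysis cases is the only
construction consistent with building each cell "from the crosstabulation
table", and it keeps cells comparable across drugs.

Filters precede the matrix: a drug needs ≥ 100 total reports and ≥ 10
event reports; a PT needs ≥ 50 reports (defaults; all three are
parameters, and the desk-scale analysis scripts lower them in proportion
to their smaller database). Filtering is monotone: raising a threshold
can only remove rows/columns.

**Clustering.** Ward linkage on Euclidean distances between drug row
vectors (`scipy.cluster.hierarchy`), flat labels by cutting at k
clusters. k defaults to 3 — the published analysis describes three
clusters in its discussion while its figure caption says two; both cuts
are one `--k` away. Determinism: scipy breaks distance ties by row
order.

**PCA.** Eigendecomposition of the column covariance matrix (columns
centred, not scaled — all columns share the lnROR scale, and scaling to
unit variance would discard the very differences in effect size the
analysis is after). Contributions are eigenvalue/trace × 100.
Sign convention: each loading vector is flipped so its largest-magnitude
entry is positive; PCA signs are otherwise software-dependent and the
published loading signs cannot be compared directly. The test suite
cross-checks scores, loadings and contributions against scikit-learn's
SVD-based PCA.

## The synthetic world

The generator emulates what matters to the pipeline about a JADER
extract, with known truth:

* **case-linked triple tables** keyed by case id, one DEMO row per case;
* **exposure**: each case × drug an independent Bernoulli draw with the
  drug's marginal usage probability;
* **events**: odds(case, pt) = baseline_odds(pt) × Π multiplier(drug, pt)
  over the case's exposed drugs; P = odds/(1+odds). Under this model the
  true reporting odds ratio of an associated pair *equals* the
  multiplier, so the estimator can be audited for calibration. A
  multiplier of 0 makes the event impossible for exposed cases;
* **background rows**: every case carries one background medication and
  one background event from pools outside any study set. A real report
  always names at least one drug and one reaction; without these rows the
  case-id join would silently condition on exposure/event status and bias
  every ROR (observed at roughly 2× attenuation before the fix);
* **mess**: duplicate rows (default rate 0.05) and per-case collapsing of
  multi-row DRUG blocks into one ";"-joined row (default rate 0.5,
  reflecting how pervasive merged fields are in real exports), plus
  missing sex/age as empty strings and coarse age tokens;
* **demographics**: slight female excess, age mass in the 60s–80s, a few
  percent coarse/missing — chosen once as a plausible SRS population; no
  demographic effect on events is modelled, so demographic comparisons on
  synthetic data are negative controls.

Mess is drawn from an RNG stream spawned independently of the core
draws, which yields the *mess-neutrality* invariant: the analysis table
built from a messy database equals the one from the mess-free database of
the same seed. The test suite asserts this equality exactly.

What the generator does **not** emulate: reporting bias mechanisms,
dose/route effects, time trends, Japanese text normalisation, and
record-level inconsistencies that are not exact duplicates. A green
pipeline on synthetic data therefore establishes correctness of the
*computation*, not robustness to every pathology of real exports.

**Calibration.** The recovery experiment (`srs_signal.recovery`) runs the
full pipeline on 50 seeds × 50,000 cases with one association per drug
(multipliers 2, 5, 10; exposure 6%, baseline 0.4%, so the weakest pair
expects ~24 exposed-event cases). Acceptance requires 95% CI coverage of
each injected multiplier in 88–100% of seeds and the multiplier-10 drug
flagged as a signal in every seed.

## Reference data and their limits

The shipped reference tables are printed summaries of the published JADER
2004-04..2022-06 corticosteroid–glaucoma screen: the 47-drug panel, the
32-PT glaucoma event set (two garbled printed spellings shipped cleaned
with the originals as synonyms), per-PT report counts, the 47-row
ROR/CI/p table, the report counts of the 13 drugs that entered the
published clustering, and the three demographic 2×2 tables. The raw
database itself is download-only and not redistributable, so the
published per-drug RORs, dendrogram geometry and PCA loadings cannot be
recomputed here; what *is* checked end to end is every derivable number:
the three demographic p-values (reproduced to printed precision), the
28-of-47 signal count, and the five PTs passing the ≥50-report filter.
Known blemishes of the printed record, preserved as shipped: several rows
pair large RORs whose CIs exclude 1 with p = 1.000 (internally
inconsistent as printed; not used as checks); the clustering stage is
described as 14 drugs but its report-count table lists 13; one
open-angle-glaucoma count is quoted as 42 in prose and 41 in the table.

## Numerical choices

* z = 1.959964 for 95% intervals; p-values never clamped except −log₁₀ p
  capped at 320 on floating underflow (with a warning).
* Ties in sorted screen output: ln ROR descending, then drug name.
* `alpha = 0` is accepted as a vacuous criterion (zero signals) though the
  pipeline config requires 0 < alpha < 1.
* Eigenvalues are clipped at zero before computing contributions; a zero
  covariance trace raises a degenerate-input error rather than dividing
  by zero.
* All seeds flow through `numpy.random.SeedSequence`; derived seeds stay
  below 2³¹.
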