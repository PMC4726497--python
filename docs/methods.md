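# Methods

This note documents the models, defaults and numerical choices behind
`cnotscreen`, and what the synthetic-data generator does and does not
emulate.

## Motif model

Motifs are one or more IUPAC-degenerate RNA strings (minimum length 4).
Scanning is exact string matching on the mRNA sense strand with
overlapping occurrences all counted; coordinates are 0-based half-open.
`N` bases in a sequence match no pattern code, a conservative choice
that never inflates site counts. The shipped consensus defaults are
literature-standard and fully overridable via a YAML config:

| motif | pattern(s) | bound by |
|---|---|---|
| CPE | `UUUUUAU`, `UUUUAAU` | CPEB family |
| PUM | `UGUAHAUA` | Pumilio |
| NRE | `AUUGUA` | Nanos |
| CPSF | `AAUAAA` | cleavage/polyadenylation machinery |
| ARE_permissive | `AUUUA` | AU-rich element proteins |
| ARE_stringent | `UUAUUUAUU` | AU-rich element proteins |

Published consensi for CPE/PUM/NRE vary between studies; these defaults
are a reasonable common denominator, not a claim of uniqueness.

## Differential expression and the anticorrelated call

Contrasts are oriented perturbation − control throughout, so an
mRNA destabilized by CNOT7 has t_kd > 0 (rises when the deadenylase is
depleted) and t_oe < 0. Welch's unequal-variance t with Satterthwaite
degrees of freedom is the default test; a zero-variance/equal-means
gene is defined as t = 0, p = 1 rather than NaN.

Three dysregulation rules are implemented. The default, `combined`,
tests knockdown against overexpression directly: that contrast spans
twice the perturbation effect, and with the small per-group sample
sizes typical of these designs (n = 3–4) it is the only rule with
useful power (per-contrast power at δ = 1.5, σ = 0.5, n = 4, α = 0.01
is ≈ 0.69, so requiring both per-contrast tests to pass has sensitivity
≈ 0.35, while the combined test is near 1). `both` and `any`
(per-contrast rules) are available via `--dysreg-rule`, and
Benjamini–Hochberg correction via the library API. The anticorrelated
flag always additionally requires the per-contrast sign pattern, so it
is a strict subset of the dysregulated set under every rule.

## RIP enrichment

The design has single libraries (FLAG IP, control IP, input), so the
call is a fold-change rule, not a dispersion-based test: counts are
rescaled to the mean library depth ("counts at average depth"), a
pseudocount (default 0.5, on the count scale) is added, and a gene is
enriched when FLAG/input and FLAG/control both reach the threshold
(default 2). With equal library sizes this reduces to pseudocounted
raw-count ratios, and a 0/0 gene gets fold exactly 1. The absence of a
replicate-based test is a deliberate limitation: the data cannot
support one.

## Resampling enrichment test

Null sets are drawn uniformly **without replacement** (gene sets are
sets; with-replacement sampling is available for sensitivity analysis).
The headline p-value is the add-one-smoothed empirical tail
(1 + #{null ≥ obs})/(B + 1), bounded below by 1/(B+1); the one-tailed
t-style approximation formed from the null mean and SD is reported
alongside for comparability with older resampling pipelines, but it is
anti-conservative on these discrete nulls and the enriched flag uses
the empirical p. The tested statistic defaults to the count of
motif-bearing genes; the total-site-count statistic is available since
both are recorded. Per-motif null streams derive from the master seed
keyed by the motif's name, so panel results do not depend on the order
motifs are listed. Motifs carried by fewer than 10 target genes
(configurable) are marked "not considered" rather than tested — with so
few carriers the resampled null is too coarse to interpret.

The background is the annotated gene universe as given; no GC- or
length-matched backgrounds are constructed.

## Tripartite screen and bookkeeping

`genes_with_all` is a plain conjunction over site counts ≥ 1, so it is
antitone in the motif list; the screen chain (genome → tripartite →
expressed → anticorrelated) is monotone non-increasing by construction
and validated at run time. "Expressed" is an explicit detection rule:
per-gene mean abundance above a configurable quantile of per-gene means
(default 25th percentile), since detection calls are upstream choices,
not statistics. Percentages round half-away-from-zero at caller-chosen
precision, matching both integer and one-decimal reporting styles.
Venn partitions are exact exclusive-region counts for 2 or 3 sets.

## Signature and survival

Signature weights are w_g = −Pearson r between gene g and the driver
across all samples of the perturbation matrix, so genes inversely
regulated by CNOT7 get positive weights and a high score means high
expression of the CNOT7-anticorrelated program. Zero-variance genes are
excluded with a warning. Ortholog mapping drops unmapped genes with an
explicit coverage fraction (never silently); collisions keep the
larger-|weight| entry.

Patient scores are normalized weighted sums of per-gene z-scores over
the genes available in the cohort (missing genes excluded and the
weight norm renormalized; no imputation). The median split assigns ties
to the low group — deterministic, and balanced to within one patient
for continuous scores. The group comparison is the standard unweighted
log-rank (Mantel-Cox) statistic; the implementation delegates to
`lifelines`, and the tests pin it against an independent hand recursion
over the pooled risk table to 1e-10. Cox modelling and multivariable
adjustment are out of scope.

## Synthetic data

All generators are pure functions of (config, seed); the four
modalities use independent child streams of the master seed, and
identical configs give byte-identical outputs.

* **UTRs** — i.i.d. bases from a mildly AU-rich composition
  (A 0.28, C 0.21, G 0.21, U 0.30), lengths Normal(400, 120) floored at
  20 nt. For each motif a prevalence-chosen fraction of genes receives
  one planted site: a concrete realization of a random pattern written
  at a position drawn uniformly among starts that do not overlap
  previously planted sites. Chance occurrences remain possible and
  expected; the truth table records planted sites only, and scan-level
  tests compare against a brute-force oracle rather than the truth
  table.
* **Expression** — simulated directly on the log2 scale (effects
  additive): baselines Normal(8, 1.5), three groups of n = 4, planted
  genes shifted +δ in knockdown and −δ in overexpression (defaults
  δ = 1.5, noise σ = 0.5), plus a `Cnot7` driver row shifted −2/+2 to
  record the perturbation itself.
* **RIP counts** — negative binomial with variance m + φm² (default
  φ = 0.05, the near-technical dispersion expected of libraries from
  one clonal cell preparation; φ = 0 gives the Poisson limit), gene
  abundances lognormal around mean 100, planted genes' FLAG-IP mean
  multiplied by the fold (default 4). The pipeline plants RIP
  enrichment on the anticorrelated truth genes — the direct-target
  scenario the method is looking for.
* **Cohort** — patient expression standard normal; event times
  exponential with hazard h₀·exp(β·score), h₀ set so the baseline
  median event time is a third of the follow-up horizon (default 120
  months); a censor-rate fraction of patients is censored uniformly
  before their event, and follow-up is truncated at the horizon. The
  default β = −0.7 makes the planted program protective.

What the generator does **not** emulate: probe-level microarray
structure, read-level sequencing, gene–gene correlation, UTR isoform
choice, batch effects, or any coupling between motif content and
expression response — motif planting is independent of the
anticorrelation planting, so on default pipeline output the enrichment
panel correctly reports no motif enrichment in the intersection set.
Passing tests therefore demonstrate the statistical machinery
(calibration, recovery of planted effects, exactness against oracles),
not biological realism of any particular dataset.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use desk-scale instances
chosen to keep Monte-Carlo error well inside the asserted bands:
5000-gene expression universes over 20 seeds for recovery fractions,
500 replicates at 200 resamples for calibration, 50,000 resamples for
the hypergeometric-limit check, 100 seeds for power statements, and
1000 null cohorts for log-rank calibration (Monte-Carlo SE ≈ 0.007
inside a ±0.02 band). Exactness checks (scanner vs brute force,
log-rank vs hand recursion, Venn identities) use no tolerance beyond
1e-10 floating-point slack.
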