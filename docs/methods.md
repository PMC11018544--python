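# Methods

This note documents the models behind `svcurate`, the defaults that
matter, and the choices made where the design was genuinely open. No
number quoted here is asserted as an empirical result; everything
measurable is computed by the test suite or `scripts/acceptance.py`.

## Coordinates and formats

Internally all intervals are 0-based half-open, so `svlen = end - start`
for every SV class; VCF POS is 1-based (`start = POS - 1`) and BED is
0-based half-open. SVLEN is stored as a positive magnitude for DEL, DUP
and INV alike. On VCF round trips SVLEN is authoritative for the interval
length: htslib derives a symbolic record's END as POS + SVLEN and
overrides an explicit INFO END, so reading END directly would shift every
SVLEN-bearing record by one. Files without SVLEN fall back to END.
Missing genotypes are excluded from genotype-class counts and from F_ST;
for PCA they are mean-imputed (neutral after centering).

## The filter cascade

Stages run in order — call quality (DHFFC), genotype quality (MSHQ),
genotype frequency, curation — each consuming the previous retained set,
with conservation (retained ∪ rejected = input, disjoint) asserted at
every stage. The three heuristic filters are independent per-call
predicates, so the final retained set is order-invariant; only the ledger
depends on order.

* **DHFFC** = median depth inside [start, end) divided by the median
  depth of both 1 kb flanks pooled. Median rather than mean for
  robustness to coverage spikes; pooling both flanks keeps the estimate
  usable when one flank crosses an assembly gap. Thresholds are strict
  inequalities, exactly as the filter expressions read: DEL retained iff
  DHFFC < 0.7, DUP iff DHFFC > 1.3; boundary values are rejected, and the
  behaviour is pinned by unit tests. Inversions are copy-neutral, so the
  filter does not apply and INV calls always pass. A zero flank median
  makes DHFFC undefined; such calls are retained with a warning rather
  than silently judged.
* **Site-level reduction.** The per-call threshold needs one DHFFC per
  site; per-sample values are reduced over carrier samples (genotype 1
  or 2). The default is the carrier median; `any_carrier` (minimum) and
  `all_carriers` (maximum) are exposed for users who want the
  most-supporting or most-conservative reading. Non-carriers are
  excluded because their expected fold-change is 1 regardless of the
  call's validity.
* **MSHQ** is the arithmetic mean of SHQ (1–4) over het samples, −1 when
  no sample is het. Retention is inclusive (MSHQ ≥ 3) and the −1 sentinel
  is retained, since a variant carried only by homozygotes offers no
  heterozygote evidence to judge.
* **Genotype frequency**: ≥ 3 called individuals in each genotype class.
  Only called genotypes count; missingness counts toward no class.
* **Curation** enters the cascade as a retained-id set (a consensus
  callset); an externally produced rejection list (e.g. an automated
  deep-learning curator) can be applied the same way by id.

Rejection percentages are reported with explicit denominators because the
natural conventions differ by stage (heuristic stages against the raw
callset, curator stages against the genotype-frequency subset selected
for review). `CascadeResult.denominators` carries the convention per
stage and `report.rejection_table` refuses a denominator absent from the
ledger. Percentages round half-up (1 decimal in tables, 0 for prose-style
figures); this convention reproduces every recomputable published
percentage exercised in the acceptance checks.

## Curation model

Verdicts are Yes/Maybe/No per (SV, curator). By default Yes ∪ Maybe
counts as retained — the lenient reading that favours keeping borderline
calls — with a strict Yes-only mode available. Stringency is
operationalized purely as the number of rejections; ties break
lexicographically with a logged warning. Consensus over k curators is the
intersection of the k most lenient curators' retained sets, by SV id
within a shared cohort (interval-based matching at 90% reciprocal overlap
is provided in `intervals` for merging independently generated callsets,
where ids cannot be trusted). Agreement is the percentage of the most
lenient curator's rejections co-rejected by every other curator,
undefined (None) when the lenient curator rejected nothing.

Panels sample `n_per_class` ∈ {1, 2, 3} individuals per genotype class
with replacement, concatenated in the fixed order hom-ref, het, hom-alt —
the juxtaposition that makes few-second visual review possible. Repeats
within a class are expected for singleton classes.

## Synthetic cohorts

The generator emulates a medium-coverage resequencing study of a
structured bird population; its defaults are the study conditions, chosen
once:

| parameter | default | rationale |
| --- | --- | --- |
| populations × samples | 4 × (9, 8, 8, 8) = 33 | cohort size and cluster count of the target design |
| `fst_param` F | 0.15 | differentiation of the order seen between the most distant clusters of such cohorts |
| `coverage` | 10× | the design's mean sequencing depth |
| `flank_bp` | 1000 | the DHFFC flank definition |
| true/false SVs per class | 100 / 100 | desk-scale cohort with enough sites per class for PCA/F_ST |
| size spectra (bp, log-uniform) | DEL (23, 5000), DUP (79, 8000), INV (33, 2000) | class minima follow the smallest raw calls per class; maxima keep per-base simulation cheap while spanning five of the eight size bins |
| SHQ weights (true / false hets) | (.05,.05,.45,.45) / (.45,.45,.05,.05) | 0.9 probability mass on the favoured score pair |

True SV genotypes follow the Balding–Nichols model: ancestral frequency
p ~ U(0.05, 0.95), per-population frequency Beta(p(1−F)/F, (1−p)(1−F)/F)
(degenerating to p exactly at F = 0, never dividing by zero), genotypes
Hardy–Weinberg within population. F equals the expected Weir–Cockerham
F_ST, which is what makes the parameter-recovery test meaningful. False
calls draw all genotypes independently from one global frequency
q ~ U(0.05, 0.5): no structure of any kind.

Depth is per-base Poisson(coverage × m) with m = 1 in flanks and, inside
a true SV, 1 / 0.5 / 0 (DEL) or 1 / 1.5 / 2 (DUP) for genotype 0 / 1 / 2;
inversions and false calls are m = 1 everywhere. Per-base Poisson rather
than per-window Gaussian keeps the DHFFC median well behaved at 10× and
degrades gracefully at lower coverage. True inversions therefore carry no
depth signal at all — deliberately, so the pipeline path where only
genotype-frequency and curation discriminate is exercised.

With the default SHQ weights the exact convolution tail gives
P(mean SHQ ≥ 3 | 10 hets) ≈ 0.915 for true SVs — the MSHQ filter loses a
deliberate minority of true calls, mirroring the imperfection of
genotype-quality filtering on real data. (No split of 0.9 mass over
{3, 4} can push this tail above ~0.98; the frozen test value comes from
the convolution oracle.)

Curators are Bernoulli: retain a true SV with `p_retain_true`, a false
call with `p_retain_false`; retained verdicts become Maybe with
`p_maybe_given_retain` when the curator uses the Maybe category. The
default roster of four has monotonically decreasing retention
probabilities:

| curator | p_retain_true | p_retain_false | p_maybe | uses Maybe |
| --- | --- | --- | --- | --- |
| lenient | 0.995 | 0.50 | 0.25 | yes |
| moderate | 0.98 | 0.01 | 0.20 | yes |
| strict | 0.96 | 0.005 | 0.15 | yes |
| strictest | 0.93 | 0.002 | 0.0 | no |

The sharp drop in false retention after the lenient curator encodes the
empirical observation that multi-curator studies find near-complete
(>99%) co-rejection of the obvious false positives a lenient curator
discards: under a flat Bernoulli model that observation forces the
stricter curators' false-retention rates toward zero. Under these
defaults the lenient curator's rejected set is overwhelmingly false calls
and its expected containment in the all-curator rejected intersection is
≈ 0.99 · (0.99 · 0.995 · 0.998) ≈ 0.97.

All randomness flows from the single config seed through named
`SeedSequence` sub-streams (genotypes per class, depth per call, SHQ per
call, verdicts per curator), so any sub-stream is reproducible in
isolation — depth for one call can be regenerated without rerunning the
cohort, which is also how the full-cohort annotator avoids holding
~0.5 GB of per-base profiles in memory.

What the generator does **not** emulate: read-level artefacts (mapping
ambiguity, GC bias, split-read/discordant-pair evidence), linkage
disequilibrium between sites, genotyping error correlated with depth,
curator behaviour that depends on SV size or "obviousness" gradations
among false calls. Passing tests therefore demonstrate that the pipeline
machinery is correct and recovers planted structure — not that the
thresholds are optimal for any particular real dataset.

## Population-structure validation

F_ST uses the 1984 Weir–Cockerham variance components with per-population
sample sizes, allele frequencies and observed het frequencies; both
aggregates are reported (mean of per-site ratios, and the weighted
Σa/Σ(a+b+c)) since they answer different questions and can differ
substantially. Negative per-site estimates are kept — truncation would
bias the aggregates. Monomorphic sites and degenerate designs (mean
per-population sample size ≤ 1) are flagged undefined and excluded.
Pairwise F_ST restricts to two clusters at a time, supporting tiny-n
(2 individuals per cluster) designs; correctness at tiny n is exercised
against an independently coded scalar oracle.

PCA operates on hard genotypes: columns centered at twice the allele
frequency, optional division by sqrt(2p(1−p)), full SVD. Hard-genotype
PCA replaces genotype-likelihood PCA deliberately: simulated genotypes
are known, so likelihood machinery would add nothing here. The
separation score is the mean silhouette of population labels on the first
two components — a scalar stand-in for the visual judgement that retained
variants cluster by population and rejected ones do not.

## Numerical and degenerate-input conventions

* Undefined values are explicit: NaN site DHFFC (no carrier / zero
  flank), −1 MSHQ sentinel, undefined F_ST components, None agreement.
  No threshold filter silently passes or fails an undefined value.
* Interval matching is one-to-one from the query side: each A record
  takes its best-overlap B partner (ties to the smaller B start), which
  keeps cascade counts well defined; candidate search uses an interval
  tree and is verified against a brute-force all-pairs oracle.
* Size bins are lower-exclusive, upper-inclusive on the eight edges
  {20, 100, 250, 500, 1000, 5000, 10000, 500000}, so a label like
  ">20 to 100 bp" reads as (20, 100]; lengths ≤ 20 bp are below the
  discovery floor and rejected.
* Percentage rounding is decimal half-up (never banker's rounding), via
  exact `Decimal` arithmetic.

## Problem sizes

Default cohorts are 600 calls × 33 samples (≈ 50 M Poisson draws,
a few seconds); Monte-Carlo suites use 1,000 replicates of single-sample
400–500 bp events; F_ST recovery uses 200 sites × 100 individuals. These
sizes give the stochastic checks comfortable margins (binomial standard
errors well inside the asserted bands) while keeping the whole suite fast.

## Known limitations

* Curation is simulated per call independently; no model of curator
  fatigue, image quality, or correlated mistakes.
* The interval module targets desk-scale callsets (≤ ~10⁵ records), not
  genome-wide interval joins over millions of records.
* BND/INS/complex SV records and multi-allelic sites are out of scope;
  records with other SVTYPEs are skipped on read with a warning.
* The MSHQ filter's behaviour on real data depends on the upstream
  genotyper's SHQ calibration, which the generator only caricatures.
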