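# Methods

## Scoring model

The Matching Score treats a tumour's molecular portfolio as a multiset
of countable units and a regimen as a set of drugs with curated
effective target sets. The score is the targeted fraction in percent,
with three refinements (synergy doubling, hormone-receptor add-ons, and
immune-biomarker tiers for checkpoint blockade) described in the
README. Internally scores are exact rationals (`fractions.Fraction`),
reported to one decimal; the high/low dichotomisation (`score > cutoff`,
strict) therefore never depends on floating-point rounding at the
boundary.

Counting conventions that were genuinely open, and the choices made:

- **Cross-assay duplicates.** A gene altered in both a tissue and a
  cfDNA assay yields two units by default, on the view that each test
  result reflects a possibly distinct tumour compartment. A
  `dedup_across_assays` flag collapses identical gene+class units
  across assays for sensitivity analyses.
- **Pathway collapsing.** Two same-gene same-class alterations always
  collapse to one unit. Collapsing *across* genes that hit one pathway
  requires an ontology the package does not impose; an optional
  user-supplied `pathway_map` (gene → pathway label) enables it.
- **Checkpoint blockade without a qualifying biomarker** contributes a
  zero tier: the drug behaves like any other unmatched agent.
  Two half-tier biomarkers (TMB-intermediate *and* PD-L1 low-positive)
  do not stack to 100; the tier stays at half.
- **Synergy doubling** requires both partners of a knowledge-base
  synergy pair in the regimen and applies to every matched unit of the
  shared gene (so a gene contributing two units — amplification and
  mutation — is doubled on each).
- **Hormone add-ons with no genomic units**: ER+ treated with letrozole
  and an otherwise empty profile scores 1/1 = 100%.
- **PD-L1 tiers.** Positivity is ≥ 1%; the high tier defaults to the
  standard ≥ 50% tumour-proportion-score convention and is
  configurable, since "high expression" has no universal definition.
- **TMB bins.** low < 6, intermediate 6–19.99…, high ≥ 20 mut/Mb; the
  printed integer bins (≤5 / 6–19 / ≥20) leave (5, 6) open and the gap
  is closed at 6. Driver/passenger status is deliberately ignored.

## Knowledge base

Drug → target curation is data, not code: entries carry a drug class,
a curated gene set (small molecules listed by low-IC50 targets or the
upstream gene of a directly-downstream effector, so a MEK inhibitor
lists *BRAF*), an anti-VEGF flag, and an optional synergy partner.
Two conventions are applied at lookup time rather than stored per drug:
anti-VEGF/VEGFR agents gain *TP53* (toggleable), and PARP inhibitors or
platinums gain the configurable BRCA-related set (default BRCA1/2,
PALB2, ATM, BARD1, BRIP1, RAD51C, RAD51D). The shipped mini-KB of ~20
drugs covers every class and convention; it is illustrative, not a
reconstruction of any clinical curation effort, and real analyses
should supply their own KB file (JSON/YAML, validated on load).

## Cohort analysis

Kaplan–Meier estimation, the log-rank test and Efron-ties Cox models
stand on lifelines; logistic models on statsmodels; Fisher's exact p on
scipy. The Breslow tie option is an in-house Newton–Raphson maximiser
of the Breslow partial likelihood (lifelines implements Efron only);
on tie-free data the two coincide, which the tests exploit. Odds
ratios use the Woolf log-OR interval with the Haldane–Anscombe 0.5
correction when a cell is empty. Report percentages are rounded
half-up to integers.

Degenerate inputs are handled explicitly rather than left to the
optimisers: constant covariates return HR 1 / p 1 with a
`no_information` flag; monotone partial likelihoods and separated
logistic fits are flagged with unbounded confidence intervals;
covariates with fewer than two patients per level are skipped with a
warning. The univariate screen admits covariates with p < 0.1
(strict); the multivariate step runs only when at least two covariates
pass, and includes exactly the screened covariates with no
interactions or stepwise refinement. Age is dichotomised at the cohort
median.

The ROC cutoff search evaluates candidate cutoffs (default: the unique
observed scores) under the strict `score > c` rule and maximises the
Youden index, breaking ties toward the larger cutoff; a
benefit-rate-difference criterion is available, since either could
plausibly sit behind a "maximum benefit in the higher group" cutoff
choice.

## Synthetic cohort generator

The generator's purpose is pipeline testing with realistic marginal
structure, not tumour biology. Choices and their consequences:

- **Gene presence** is an independent Bernoulli draw per gene per
  assay, with marginal frequencies matching the published per-gene
  rates for the table heads (tissue TP53 0.554, CDKN2A 0.243, KRAS
  0.203; cfDNA TP53 0.611, KRAS 0.208, PIK3CA 0.167) and an
  illustrative long tail sized so the exact Poisson-binomial median of
  the per-assay alteration count is 4 (tissue) and 2 (cfDNA), within
  the printed 0–25 / 0–9 ranges. Independent draws reproduce marginal
  frequencies exactly, which a count-distribution-first scheme
  (draw a count, then sample genes) cannot do without heavy
  calibration; the cost is the absence of mutual-exclusivity or
  co-occurrence structure — a documented limitation.
- **Biomarkers** follow the published testing rates and positivity
  proportions (TMB tested 64/97 with category probabilities
  0.625/0.281/0.094, MSI tested 55/97 with 3.6% high, PD-L1 tested
  55/97 with 30.9% ≥ 1%); values within a category are uniform over
  the category's range.
- **Regimens** follow a policy: `matched_rich` pairs drugs to sampled
  genes through the KB (adding both synergy partners, checkpoint
  blockade for immune-eligible tumours, hormone modulators for
  receptor-positive ones), `unmatched` gives non-targeting cytotoxics,
  `random` samples drugs uniformly. Scores are always computed by the
  real engine — the generator never assigns scores directly.
- **Outcomes.** PFS is exponential with the group's median (defaults
  10.4 / 2.8 months); OS adds an independent exponential
  post-progression time whose median is the OS–PFS median gap, so
  OS ≥ PFS holds by construction. Clinical benefit is Bernoulli
  (0.71 / 0.24) and the best response is assigned consistently with
  it: benefiting patients get PR, or SD with duration = PFS when
  PFS ≥ 6 months; non-benefiting patients with PFS ≥ 6 months get PD.
- **Censoring** is administrative and independent of the event
  process: follow-up ~ U(0, b], with b solved per group from
  (1 − e^{−λb})/(λb) = censoring fraction (default 0.2) for the
  group's PFS rate λ; PFS and OS are truncated at the same follow-up
  time. Dependent censoring (e.g. censoring at a uniform fraction of
  the failure time) would bias hazard-ratio recovery and is
  deliberately avoided.

Because the generator matches only published marginals, passing
pipeline tests demonstrates correct propagation of a known signal, not
fidelity to real CUP joint distributions: the true joint law of score
and outcome is not identifiable from summary statistics.

## Problem sizes and tolerances

Calibration tests use sizes at which binomial/Wald sampling error is
small relative to the asserted bands: marginal-frequency checks at
n = 5000 (2 s.e. bands, binomial 99% CIs), KM-median recovery at
n = 10 000 (±5%), Cox HR recovery at 500 patients per arm (±15%,
about two standard errors of the log-HR at ~800 events), log-rank
type-I error over 1000 null replicates of 200 per arm (accepting
0.03–0.07), and Wald CI coverage over 500 replicates at n = 500
(accepting 0.90–0.98). The grid-search Cox oracle uses a two-stage
dense grid on log-HR ∈ [−5, 5] (~10⁻⁶ resolution); engine-vs-oracle
agreement is asserted to 3 decimals on ≤ 20-patient datasets and
exactly (rational arithmetic) for the scoring engine against the
brute-force rule enumerator.

## Known limitations

- The default KB is a small illustrative curation; scores on real data
  are only as good as the supplied KB.
- Matching treats any drug–gene containment as a full match: no dose,
  resistance-mutation, or line-of-therapy awareness.
- The simulator draws genes independently and links outcome to the
  dichotomised group only (not to the continuous score), with
  exponential survival — all simplifications chosen for testability.
- RNA immune-marker levels are stored and reported but never scored.
- No competing risks, time-varying covariates, or response
  adjudication; responses are taken as given.
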