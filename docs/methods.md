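# Methods

## Model and assumptions

The pipeline targets screens with one replicate per condition and a shared
panel of conditions (drugs) profiled on the same platform. Its central
assumption is *exchangeability of a gene across conditions under the null*:
most drugs do not move most genes, so the distribution of a gene's abundance
across the whole panel estimates its unaffected behaviour, and any one
condition can be scored against it. Robust location/scale estimates (median,
MAD) keep that background honest when a minority of conditions do carry
signal — a handful of true perturbations inflate a standard deviation but
barely move a median.

The second assumption is that regulator programs act coherently: when a drug
activates (inhibits) an upstream regulator, its annotated targets move in the
direction given by the product of the edge sign and the regulator state. The
activation z-score is the normalized sum of those products over the
differentially expressed targets; with unit weights it equals
(consistent − inconsistent)/√overlap, so |z| ≤ √overlap with equality only
for perfect coherence, and 5 perfectly coherent targets (√5 ≈ 2.24) is the
smallest all-consistent program that can clear the |z| > 2 gate — one reason
the robust-network rule asks for at least five.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `cpm_threshold` | 1 (CPM) | keep genes with mean CPM strictly above this |
| pseudocount | 1 | added before log2 so zeros are defined |
| `alpha_deg` | 0.05 | adjusted-p cutoff defining a DEG |
| `bh_scope` | `per_drug` | BH family: genes within one drug (each drug is one experiment); `global` pools all pairs |
| `z_state_threshold` | 2 | strict cut for Activated / Inhibited |
| `p_overlap_threshold` | 0.05 | raw overlap-p significance (unadjusted across regulators by default; BH per drug behind a flag) |
| `min_consistent_targets` | 5 | significant, direction-consistent targets required for a robust network |
| `count_rule` | `consistent` | what the ≥5 rule counts; `significant` relaxes it to significance alone |

All thresholds are applied strictly (`>`, `<`): a z of exactly ±2 predicts no
state and a p_adj of exactly 0.05 is not significant, matching the DEG
definition p_adj < 0.05.

Direction consistency is operationalized as
`edge_sign × DEG direction = sign(activation z)`; targets whose robust z is
exactly 0 are excluded from direction scoring rather than counted against
consistency. Concordance between a regulator's own expression and its
predicted state is reported (`concordant` / `discordant` / `unknown` when the
regulator is unmeasured) but never gates robustness: real programs can score
while the regulator's own transcript is flat, absent from the panel, or even
moving opposite to the naive expectation.

## Prioritization order

DEGs are tiered `network` (member of ≥1 robust network) or `singleton`, and
ordered within tier by |activation z| of the best member network
(descending), then overlap p (ascending), then gene id. The lexical tie-break
makes the order total and deterministic, which matters for reproducible
reports; nothing scientific hangs on it.

## Synthetic screens

The generator emulates the screen design the pipeline is built for: per-gene
baselines (log2 CPM ~ Normal(7, 1), so every gene passes the CPM filter and
baseline choice never confounds power comparisons), i.i.d. Gaussian noise on
the log2 scale per (gene, condition), and two kinds of planted signal of
identical magnitude — regulator programs (every target of an activated
program shifts by `effect_size × edge_sign × activation_sign`) and singleton
DEGs planted in genes the knowledge base never mentions. Because the two
strata differ *only* in network membership, any difference in downstream
true-positive rates isolates the value of network membership itself.

Defaults are one screen design used throughout: 2000 genes × 20 drugs, ten
regulator programs of eight disjoint targets (25% inhibiting edges), ten
singletons per drug, noise SD 0.5 log2 units and effect size 2.5 (five noise
SDs). Gaussian noise is chosen because the downstream robust z + normal-tail
p assumes it; program targets are disjoint so each program's ground truth is
unambiguous; each regulator acts in exactly one drug (round-robin) with a
random ±1 sign. The matrix is emitted as CPM = 2^x − 1, the exact inverse of
the DE stage's log2(CPM + 1), so planted shifts survive the round trip
exactly. All randomness flows from a single master seed through named
substreams (knowledge base; screen setup; one stream per drug column), making
every artifact byte-reproducible.

What the generator does **not** emulate: read-count sampling, library-size or
batch effects, correlated noise between co-regulated genes, overlapping
programs, or dose structure. Passing tests on these screens therefore shows
the pipeline's logic and calibration under its own assumptions, not
performance on real count data.

## Numerical choices

* Robust z uses the 1.4826 MAD consistency factor; when a row's MAD is 0 the
  sample SD replaces the scaled MAD, and a fully constant row scores 0
  everywhere. With an n−1-identical-values row this fallback means the
  outlier's score saturates near √n instead of growing without bound —
  unbounded growth requires a bulk with nonzero MAD.
* p = 2Φ(−|z|) is clipped below at the smallest positive float so BH input
  stays in (0, 1] even for |z| ≳ 38.
* The overlap p-value is the exact hypergeometric upper tail
  (`scipy.stats.hypergeom.sf`, with a log-space fallback against underflow);
  it agrees with brute-force enumeration to 12 significant digits for all
  N ≤ 30 (tested exhaustively).
* The drug's own column is included in its background; with panels of ~20+
  conditions one column barely perturbs a median.

## Known limitations

**Finite-panel anticonservativeness.** The normal-tail p-value treats the
robust z as standard normal, but with 20 conditions the median and MAD are
estimated from 20 values and their sampling noise fattens the tails: on
pure-noise screens the pipeline's own null experiment measures a rejection
rate of ~0.073 at p < 0.05 (400 000 pairs) rather than 0.05, and BH calls
~0.5% of null pairs significant rather than ~0. The inflation shrinks roughly
as 1/(number of conditions) and is an order of magnitude smaller at panel
sizes in the hundreds, where this design is meant to operate. Within the
package this matters little for the *relative* claims (null false positives
land overwhelmingly in the singleton tier, which is the point of the
contrast), but absolute error rates from small panels should be read as
optimistic. A permutation-calibrated or t-tail p-value would be the natural
extension.

**Other limitations.** Gene identifiers are opaque strings — no
ortholog/symbol mapping across species. URA is single-layer: no depth-2
causal reasoning, no literature-bias correction. Edge weights default to 1;
published knowledge bases with calibrated confidence weights will give
different activation z magnitudes than the unit-weight form. The ≥5 rule
counts significant-and-consistent targets (the conjunctive reading); the
disjunctive reading is available via `count_rule="significant"`.
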