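# Methods

## The transfer model

The package treats interface residue prediction as label transfer through
pairwise sequence alignment. A *template* is a protein chain from a solved
multi-chain structure whose interface residues are known; given a BLASTP
alignment between a query and a template, the template's per-residue labels
are projected onto the query's coordinates column by column. The modelling
assumption is the empirical one that motivates the method: interface
residues are conserved among sufficiently close homologs, and alignment
statistics predict *how* conserved. The degree of conservation of one
template against one query is quantified by the interface-conservation (IC)
score, defined as the Matthews correlation coefficient between the
transferred labels and the query's true labels, with `?` positions excluded
pairwise.

Two prediction settings are supported. The non-partner-specific (NPS)
setting transfers the union of a template's interfaces over all its
partners; it answers "which residues of this protein ever bind anything".
The partner-specific (PS) setting operates on query pairs A–B and only
transfers labels from homo-interologs — template pairs A′–B′ that interact
within one complex — using A′'s interface *with B′* specifically. The PS
setting exists because transient interfaces are typically specific to one
partner: the union of a transient binder's interfaces is poorly conserved
even when each partner-specific interface is well conserved.

## Interface definition and label derivation

A residue is labelled an interface residue when both of the following hold:

* **Surface**: relative solvent-accessible area (RASA) ≥ 5% (0.05),
  computed on the isolated chain — accessibility is assessed before asking
  about contacts, so residues buried within their own chain can never be
  interfaces, and the definition does not depend on which partners happen
  to be present in the file.
* **Contact**: any atom within 4 Å (Euclidean, all atoms present; heavy
  atoms when hydrogens are absent) of any atom of a partner chain. For NPS
  labels every other chain is a partner; PS labels restrict the partner
  set to one chain.

SASA uses Shrake–Rupley sphere sampling with a deterministic golden-spiral
point lattice (default 256 points per atom, probe 1.4 Å, van der Waals
radii by element). RASA divides the residue's summed atom SASA by the
theoretical Gly-X-Gly maximum of its residue type (Tien et al. 2013
values); unknown residue types fall back to the table median with a
warning. Exposed termini can exceed RASA 1 slightly; that is harmless
because only the 0.05 threshold matters. The production contact scan uses
a k-d tree; tests assert exact agreement with a brute-force all-pairs scan.

Residues without coordinates are labelled `?` and abstain from everything
downstream: they cast no votes, and they are excluded pairwise from IC and
evaluation counts. This choice means missing data can never act as negative
evidence.

Structure-to-sequence mapping reads PDB MODEL 1, maps ATOM residues to the
full (SEQRES or user-provided) sequence by residue numbering, and falls
back to a local pairwise alignment when numbering is inconsistent. This is
a deliberate simplification of curated mapping databases: for pathological
PDB numbering the alignment fallback can misplace residues that a curated
mapping would fix.

Templates are retained only when the structure is X-ray with resolution
≤ 3.5 Å and the chain has at least 3 interface residues; each rejection is
reported with the rule that fired.

## Homology zones

Zone thresholds (all comparisons inclusive, as printed in the source
tables):

| zone | log(EVal) ≤ | Positive ≥ | NPS: log(LAL) ≥ | PS: Frac_AA′, Frac_BB′ ≥ |
|---|---|---|---|---|
| Safe | −100 | 80% (PS: 70%) | 5.2 | 80% |
| Twilight 1 | −50 | 65% (PS: 60%) | 4 | 60% |
| Twilight 2 | 1 | 60% (PS: 55%) | 4 | 40% |
| Dark | 1 | 0 | 0 | 0 |

Classification is strictest-first, so overlapping rows are harmless.
Natural logarithms are used throughout (the printed conversions are
ln-consistent: log(EVal) = −50 ↔ 1.93e−22, log(LAL) = 4 ↔ 55 residues);
log(EVal) is set to −450 when EVal = 0. Note the zone tables cap log(EVal)
at 1 while the BLASTP search itself admits EVal ≤ 10 (ln 10 ≈ 2.30): hits
in that sliver belong to no zone and are unusable, which we treat as the
operative definition. Thresholds are configurable (YAML, `--zones`)
because the defaults are calibrated on transient complexes and are
deliberately conservative; obligate queries tolerate looser bounds.

For PS pairs, log(EVal), Positive Score and log(LAL) are arithmetic means
over the A–A′ and B–B′ alignments (the −450 floor is applied per chain
before averaging). Frac_AA′ is the *product* of the two length fractions
LAL/len(A) · LAL/len(A′) — the only combination the source analysis
exhibits — and is compared against the percent thresholds after ×100. A
`frac_combine="min"` switch provides the alternative reading, since the
defining equation's prose is truncated in the source; this is the one
genuine ambiguity in the PS statistics and both variants are testable.

## IC regression and template selection

Within the chosen zone, templates are ranked by a linear IC model:

* NPS: IC = −0.5655 − 0.0004·log(EVal) + 0.0037·Positive + 0.1057·log(LAL)
* PS: IC = −0.505 + 0.001·avg log(EVal) + 0.009·avg Positive
  + 0.341·Frac_AA′ + 0.205·Frac_BB′

Inputs are on the scales above (percent 0–100 for positive scores,
fractions 0–1) — required for the printed coefficients to produce IC values
in a plausible [−1, 1] neighbourhood. Predictions are not clipped because
the model is used only for ranking. Raw (unstandardised) inputs are
assumed; the printed coefficient magnitudes are consistent with that. The
estimator refits by OLS (statsmodels), reporting coefficients, standard
errors and t-values; at least p + 2 observations and a full-rank design are
required, and rank deficiency raises an error naming the collinear columns.

Ties in predicted IC break by lower EVal, then template id, so output is
byte-deterministic. When a query–template pair has several HSPs, only the
one with the best predicted IC votes (one vote per template per position).
At most K = 10 templates are consulted; the cascade is Safe → Twilight 1 →
Twilight 2 → Dark for NPS (Twilight split strictest-first to preserve the
monotone thresholds) and never Dark for PS. A query position's vote score
is positives / votes cast — abstentions do not enter the denominator — and
a score ≥ 0.5 (ties included) calls an interface. Positions with zero votes
are called 0 but flagged (`n_votes = 0`) so evaluations may exclude them;
the default evaluation keeps them as 0.

## Homolog filtering

Before prediction, hits are removed when they are exact self-hits, or share
≥ 95% alignment identity *and* the query's species tag (the conjunction
matters: a 97%-identical template from another species is kept), or fail
the structure-quality rule above. For PS, additionally the query pair's own
complex is excluded, as is any interolog whose complex resolution exceeds
3.5 Å, and the ≥ 95%-plus-species rule applies to either chain of the
pair. Every removal is logged with its reason.

## Evaluation measures

Per protein: sensitivity TP/(TP+FN), specificity TP/(TP+FP) — i.e.
*precision*, following the naming convention of the interface-prediction
literature, not the true-negative rate — accuracy, and Matthews CC.
Protein-based overall measures are unweighted means over proteins;
residue-based measures pool counts first. Ratios with zero denominators are
undefined: they are reported as None and excluded from averages with the
exclusion count retained, rather than coerced to an arbitrary 0 that would
bias averages. Evaluation runs over the full sequence, not surface residues
only, which is the harder (sequence-based) convention. Precision–recall
sweeps use as thresholds exactly the distinct vote scores present, since
majority voting over ≤ 10 templates yields few distinct scores.

## Synthetic data: what it emulates and what it does not

The generator exists so that every stage is testable offline with
analytically known truth.

* `make_complex` builds straight pseudo-atom chains (CA plus one side-chain
  pseudo-atom, 5 Å spacing) stacked 10 Å apart, with a contact patch
  lowered to 3.2–3.8 Å from the partner; all non-patch inter-chain pairs
  stay > 6 Å. Defaults: 2 chains, lengths 30–60, patch 4, resolution 2.0 Å.
  The construction guarantees the interface labels exactly, which is the
  point: it exercises the geometry code, not protein physics. It does not
  emulate packing, secondary structure, or partially buried interfaces.
* `mutate_homolog` applies point substitutions (interface positions at
  `sub_rate · (1 − bias)`, so bias = 1 freezes the interface) and short
  indels, emits the exact alignment, and fabricates the BLAST record from
  it. A substituted interface residue loses its label with probability 0.5,
  so transferred-label conservation degrades with divergence as it does in
  real families. Synthetic EVal = exp(ln(Lq·Lt) − 2·nident), exponent
  clamped at −450 — a monotone stand-in chosen only to place fixtures in
  intended zones, with no Karlin–Altschul fidelity; real BLAST EVals are
  used whenever real BLAST output is parsed.
* `make_ps_scenario` gives query A two disjoint 8-residue interfaces, one
  used with partner B and one with a decoy partner C, through two
  homo-interolog complexes, enabling the partner-specificity property test.

Consequently, passing tests show the pipeline is *algorithmically* correct
(labelling, zoning, ranking, voting, scoring match their independent
oracles exactly), and that transfer quality responds to divergence as
designed. They do not certify accuracy on real proteins, which depends on
real conservation patterns and real BLAST statistics.

## Numerical and design choices

* Natural logs everywhere; log(EVal) floor −450 applies only to EVal = 0
  (a positive EVal below e⁻⁴⁵⁰ would keep its own log, but doubles
  underflow long before that matters).
* Percent-vs-count BLAST columns: `pident`/`ppos` are converted to counts
  by rounding pct·LAL/100 to the nearest integer.
* LAL follows the BLAST `length` field: alignment columns including gaps.
* The matrix/gap-cost recommendation by query length resolves the two
  boundary lengths shared by adjacent published rows (50 and 85) to the
  later row, making the ranges disjoint: [1,34] PAM30 (9,1), [35,49] PAM70
  (10,1), [50,84] BLOSUM80 (10,1), [85,∞) BLOSUM62 (10,1).
* Shrake–Rupley is deterministic for a fixed `n_points`; 256 points keeps
  single-residue RASA within ~3% of a 960-point reference at a quarter of
  the cost, and only the 5% threshold consumes the value.
* Acceptance-script problem sizes (40 labelling complexes, 200 vote
  recounts, 25 end-to-end queries of length 180–220 with 2–5 homologs at
  25% substitution, OLS at n = 5000) were chosen as the smallest sizes at
  which the agreement rates and recovery errors are stable across seeds.

## Known limitations

* No mmCIF input; PDB MODEL 1 only; curated ATOM↔SEQRES mapping databases
  are approximated by numbering plus alignment fallback.
* Hydrogens are used in the 4 Å scan when present, so protonated and
  unprotonated structures can label borderline contacts differently.
* The complex index (which template chains interact in which complex) is
  required input for PS prediction; deriving it from the PDB at large is
  out of scope.
* Zone boundaries and IC coefficients are fixed defaults, not re-derived
  from data; refitting the IC model is supported but re-deriving zones is
  not.
* NMR-only templates are excluded wholesale rather than assessed per
  model.
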