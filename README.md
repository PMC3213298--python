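# homppi

Sequence-homology-based prediction of protein–protein interface residues.

Interface residues — the residues of a protein that contact a binding
partner — are conserved among close sequence homologs, strongly enough that
they can be *transferred*: if a homolog of your query sits in a solved
complex, its known interface residues, projected through the pairwise
alignment, are a good prediction for the query. `homppi` implements two
predictors built on that idea:

* **NPS** (non-partner-specific): predicts the union of a query's interface
  residues over all partners, from BLASTP hits against a library of
  template chains with structure-derived interface labels.
* **PS** (partner-specific): given a query pair A–B, finds
  *homo-interologs* — pairs A′–B′ of homologs of A and B that interact
  within one solved complex — and transfers A′'s interface *with B′* onto
  A. Transient interfaces are highly partner-specific, so this variant is
  the right tool when the partner is known.

The package is aimed at structural bioinformaticians who have query
sequences, BLASTP tabular output, and either a labelled template table or
multi-chain PDB files to derive one from.

## Method

**Interface definition.** A residue is a surface residue when its relative
solvent-accessible area (RASA, computed on the isolated chain by
Shrake–Rupley sampling and normalised by Gly-X-Gly maxima) is ≥ 5%; it is
an interface residue when it is a surface residue with any atom within 4 Å
of any atom of a partner chain. Labels live on full-sequence coordinates as
`1` / `0` / `?` (missing coordinates).

**Homology zones.** Each query–template alignment is summarised by
log(EVal) (natural log, floored at −450 for EVal = 0), the Positive Score
(percent of positive-scoring alignment columns) and log(LAL) (local
alignment length). Thresholds on these statistics bin hits into Safe,
Twilight (two bands) and Dark zones of expected interface conservation;
e.g. the Safe zone requires log(EVal) ≤ −100, Positive Score ≥ 80% and
log(LAL) ≥ 5.2. The PS zones constrain instead the pair averages and the
combined alignment-length fractions Frac_AA′, Frac_BB′.

**Ranking and voting.** Within the strictest non-empty zone, candidate
templates are ranked by a linear interface-conservation (IC) model,

    IC_nps = β₀ + β₁·log(EVal) + β₂·PositiveScore + β₃·log(LAL)

(with published default coefficients; an analogous 5-term model for PS),
and at most K = 10 are kept. Each template votes at every aligned query
position — positive if its residue is labelled interface, negative if not,
abstaining on gaps and missing coordinates — and a position is called an
interface residue when the vote score (positives / votes cast) is ≥ 0.5.
PS prediction uses Safe and Twilight interologs only; a query with no
usable template in any zone is reported as *not predicted* rather than
all-negative.

## Worked example

Everything below runs offline on generated data:

```bash
homppi simulate --scenario nps --seed 11 --out demo/
homppi predict-nps --query demo/query.fasta --blast demo/hits.tsv \
    --templates demo/labels.tsv --out demo/pred.tsv
```

which prints

```
query: zone=twilight1 templates=1 interface_calls=4
```

meaning: the single synthetic homolog fell in Twilight Zone 1 (its
alignment statistics passed log(EVal) ≤ −50, Positive Score ≥ 65%,
log(LAL) ≥ 4 but missed the Safe thresholds), one template voted, and 4
query positions received vote score ≥ 0.5. `demo/pred.tsv` lists, per
position: residue, vote score, binary call and the number of votes cast.

The same workflow in Python:

```python
from homppi import NPSInterfacePredictor
from homppi.simulate import make_ps_scenario

sc = make_ps_scenario(seed=5)
pred = NPSInterfacePredictor().fit(sc.templates).predict([sc.query_a])[0]
print(pred.zone_used, sum(pred.calls))   # twilight1 15
```

`predict-ps`, `label-structure` (PDB → label table) and `evaluate`
(per-protein and pooled sensitivity / precision / accuracy / Matthews CC,
plus precision–recall sweeps over the vote-score threshold) complete the
CLI; every command is a thin wrapper over the library.

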