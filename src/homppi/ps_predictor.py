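"""Partner-specific interface prediction through homo-interologs.

For a query pair A-B, a homo-interolog is a pair A'-B' of homologs of A and
B that interact within one solved complex.  The predictor enumerates
homo-interologs from the two BLAST hit lists and a complex index, filters
them (query's own complex, near-identical same-species pairs, resolution),
computes combined pair statistics, keeps Safe/Twilight-zone pairs only,
ranks them by the PS interface-conservation model, and majority-votes A's
interface *with B* from the partner-specific labels of the A' chains (and
symmetrically for B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from sklearn.base import BaseEstimator

from homppi.blast_io import AlignmentRecord, compute_stats
from homppi.ic_model import InterfaceConservationRegressor
from homppi.nps_predictor import Prediction, Query, TemplateChain, vote_transfer
from homppi.structure_interface import LabelTrack
from homppi.zoning import PS_ZONES, PSStats, Zone, ZoneThresholds, classify_ps

__all__ = [
    "ComplexIndex",
    "InterologPair",
    "PSInterfacePredictor",
    "find_interologs",
    "ps_stats",
    "predict_ps",
]

#: Zones PS prediction may use: Dark-zone homo-interologs are never trusted.
PS_PREDICTION_ZONES = (Zone.SAFE, Zone.TWILIGHT1, Zone.TWILIGHT2)


class ComplexIndex:
    """Which template chains interact within which solved complex."""

    def __init__(self):
        self._pairs: set[tuple[str, str, str]] = set()
        self._members: dict[str, set[str]] = {}

    def add_interaction(self, complex_id: str, chain_a: str, chain_b: str) -> None:
        self._pairs.add((complex_id, chain_a, chain_b))
        self._pairs.add((complex_id, chain_b, chain_a))
        self._members.setdefault(complex_id, set()).update((chain_a, chain_b))

    def interact(self, complex_id: str, chain_a: str, chain_b: str) -> bool:
        return (complex_id, chain_a, chain_b) in self._pairs

    def complexes_of(self, chain_id: str) -> set[str]:
        return {cid for cid, members in self._members.items() if chain_id in members}

    def shared_complexes(self, chain_a: str, chain_b: str) -> set[str]:
        return self.complexes_of(chain_a) & self.complexes_of(chain_b)

    def iter_rows(self):
        for complex_id in sorted(self._members):
            for chain in sorted(self._members[complex_id]):
                partners = sorted(b for cid, a, b in self._pairs
                                  if cid == complex_id and a == chain)
                yield complex_id, chain, ",".join(partners)


@dataclass(frozen=True)
class InterologPair:
    """One homo-interolog A'-B' of the query pair A-B.

    Label tracks are partner-specific: ``labels_a_prime`` marks the
    interface of A' *with B'* only (not A''s union interface), and
    symmetrically for B'.
    """

    aln_a: AlignmentRecord
    aln_b: AlignmentRecord
    complex_id: str
    template_a: TemplateChain
    template_b: TemplateChain
    stats: PSStats = field(compare=False)

    @property
    def labels_a_prime(self) -> LabelTrack:
        return self.template_a.labels

    @property
    def labels_b_prime(self) -> LabelTrack:
        return self.template_b.labels


def ps_stats(aln_a: AlignmentRecord, aln_b: AlignmentRecord,
             frac_combine: str = "product") -> PSStats:
    """Combined pair statistics for the two alignments A-A' and B-B'.

    ``avg_log_eval``/``avg_positive``/``avg_log_lal`` are arithmetic means
    of the per-chain values (log EVal already floored at -450 for exact
    hits).  ``frac_aa`` combines the two length fractions of the A-A'
    alignment -- their product by default, their minimum with
    ``frac_combine="min"`` -- and likewise ``frac_bb``.
    """
    sa, sb = compute_stats(aln_a), compute_stats(aln_b)
    if frac_combine == "product":
        frac_aa = sa.frac_query * sa.frac_template
        frac_bb = sb.frac_query * sb.frac_template
    elif frac_combine == "min":
        frac_aa = min(sa.frac_query, sa.frac_template)
        frac_bb = min(sb.frac_query, sb.frac_template)
    else:
        raise ValueError(f"frac_combine must be 'product' or 'min', got {frac_combine!r}")
    return PSStats(
        avg_log_eval=(sa.log_eval + sb.log_eval) / 2.0,
        avg_positive=(sa.positive_score + sb.positive_score) / 2.0,
        frac_aa=frac_aa,
        frac_bb=frac_bb,
        avg_log_lal=(sa.log_lal + sb.log_lal) / 2.0,
    )


def find_interologs(
    query_a: Query,
    query_b: Query,
    hits_a: Sequence[tuple[TemplateChain, AlignmentRecord]],
    hits_b: Sequence[tuple[TemplateChain, AlignmentRecord]],
    complex_index: ComplexIndex,
    query_complex_id: Optional[str] = None,
    identity_cutoff: float = 95.0,
    max_resolution: float = 3.5,
    frac_combine: str = "product",
) -> list[InterologPair]:
    """Enumerate homo-interologs of the query pair.

    A candidate (A', B') qualifies when both chains belong to, and interact
    within, one complex.  Excluded: the query's own complex; pairs where A
    and A' (or B and B') share >= 95% identity *and* species; complexes
    with resolution worse than 3.5 A.  Hits whose template carries labels
    for a different partner than the candidate mate are skipped, so the
    transferred labels are always the A'-with-B' interface.
    """
    out: list[InterologPair] = []
    for ta, ra in hits_a:
        for tb, rb in hits_b:
            for complex_id in sorted(complex_index.shared_complexes(
                    ta.template_id, tb.template_id)):
                if not complex_index.interact(complex_id, ta.template_id, tb.template_id):
                    continue
                if query_complex_id is not None and complex_id == query_complex_id:
                    continue
                if ta.complex_id not in (None, complex_id) or \
                        tb.complex_id not in (None, complex_id):
                    continue
                if ta.partner_id not in (None, tb.template_id):
                    continue
                if tb.partner_id not in (None, ta.template_id):
                    continue
                if _near_identical_same_species(query_a, ta, ra, identity_cutoff) or \
                        _near_identical_same_species(query_b, tb, rb, identity_cutoff):
                    continue
                if _bad_resolution(ta, max_resolution) or _bad_resolution(tb, max_resolution):
                    continue
                out.append(InterologPair(
                    aln_a=ra, aln_b=rb, complex_id=complex_id,
                    template_a=ta, template_b=tb,
                    stats=ps_stats(ra, rb, frac_combine=frac_combine)))
    return out


def _near_identical_same_species(query: Query, template: TemplateChain,
                                 rec: AlignmentRecord, cutoff: float) -> bool:
    identity = 100.0 * rec.n_identical / rec.lal
    return (identity >= cutoff and bool(template.species)
            and template.species == query.species)


def _bad_resolution(template: TemplateChain, max_resolution: float) -> bool:
    return template.resolution is None or template.resolution > max_resolution


def predict_ps(
    query_a: Query,
    query_b: Query,
    interologs: Sequence[InterologPair],
    model: Optional[InterfaceConservationRegressor] = None,
    zones: tuple[ZoneThresholds, ...] = PS_ZONES,
    k: int = 10,
) -> tuple[Prediction, Prediction]:
    """PS predictions for both chains of the query pair.

    Cascades Safe -> Twilight-1 -> Twilight-2 (never Dark); within the
    chosen zone ranks homo-interologs by predicted PS interface
    conservation and keeps at most ``k``; then votes exactly as the NPS
    transfer but with partner-specific labels.
    """
    model = model or InterfaceConservationRegressor(kind="ps")
    len_a, len_b = len(query_a.sequence), len(query_b.sequence)

    by_zone: dict[Zone, list[InterologPair]] = {}
    for pair in interologs:
        zone = classify_ps(pair.stats, zones)
        if zone is not None:
            by_zone.setdefault(zone, []).append(pair)

    for zone in PS_PREDICTION_ZONES:
        if zone not in by_zone:
            continue
        pairs = by_zone[zone]
        ranked = sorted(pairs, key=lambda p: (
            -model.predict_one(p.stats),
            max(p.aln_a.eval, p.aln_b.eval),
            p.template_a.template_id, p.template_b.template_id))[:k]
        pred_a = _vote(query_a.query_id, len_a,
                       [(p.template_a, p.aln_a) for p in ranked], zone, ranked)
        pred_b = _vote(query_b.query_id, len_b,
                       [(p.template_b, p.aln_b) for p in ranked], zone, ranked)
        return pred_a, pred_b
    return (Prediction.not_predicted(query_a.query_id, len_a),
            Prediction.not_predicted(query_b.query_id, len_b))


def _vote(query_id, length, template_alignments, zone, ranked) -> Prediction:
    scores, calls, n_votes = vote_transfer(length, template_alignments)
    used = [f"{p.complex_id}:{p.template_a.template_id}-{p.template_b.template_id}"
            for p in ranked]
    return Prediction(query_id=query_id, scores=scores, calls=calls,
                      n_votes=n_votes, zone_used=zone, templates_used=used,
                      predicted=True)


class PSInterfacePredictor(BaseEstimator):
    """Scikit-learn-style wrapper around the PS transfer algorithm.

    ``fit`` registers the partner-specific template library and complex
    index; ``predict`` maps query pairs (each chain carrying its BLAST
    records) to per-chain predictions.
    """

    def __init__(self, k: int = 10, zones: tuple[ZoneThresholds, ...] = PS_ZONES,
                 model: Optional[InterfaceConservationRegressor] = None,
                 frac_combine: str = "product"):
        self.k = k
        self.zones = zones
        self.model = model
        self.frac_combine = frac_combine

    def fit(self, templates: Sequence[TemplateChain],
            complex_index: ComplexIndex) -> "PSInterfacePredictor":
        # PS consumes partner-specific tracks; a template may appear once
        # per partner.
        self.templates_ = [t for t in templates if t.partner_id is not None]
        self.complex_index_ = complex_index
        return self

    def predict(self, query_pairs: Sequence[tuple[Query, Query]],
                query_complex_ids: Optional[Sequence[Optional[str]]] = None
                ) -> list[tuple[Prediction, Prediction]]:
        if not hasattr(self, "templates_"):
            raise RuntimeError("predictor is not fitted; call fit(templates, index) first")
        model = self.model or InterfaceConservationRegressor(kind="ps")
        by_id: dict[str, list[TemplateChain]] = {}
        for t in self.templates_:
            by_id.setdefault(t.template_id, []).append(t)
        out = []
        for i, (qa, qb) in enumerate(query_pairs):
            own = query_complex_ids[i] if query_complex_ids else None
            hits_a = [(t, r) for r in qa.records for t in by_id.get(r.template_id, [])]
            hits_b = [(t, r) for r in qb.records for t in by_id.get(r.template_id, [])]
            pairs = find_interologs(qa, qb, hits_a, hits_b, self.complex_index_,
                                    query_complex_id=own,
                                    frac_combine=self.frac_combine)
            out.append(predict_ps(qa, qb, pairs, model=model,
                                  zones=self.zones, k=self.k))
        return out
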