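"""Non-partner-specific interface prediction by homology transfer.

Given a query sequence and its BLASTP hits against a library of template
chains with known interface residues, the predictor (1) filters templates
(self-hits, near-identical same-species hits, unreliable structures),
(2) classifies each hit into a homology zone and keeps the strictest
non-empty zone, (3) ranks that zone's hits by predicted interface
conservation keeping at most K = 10, and (4) labels each query position by
majority vote of the aligned template labels: vote score = positive votes /
votes cast, interface call at score >= 0.5.  Templates abstain at positions
with missing coordinates (``?``) or alignment gaps, so missing data never
counts as negative evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from sklearn.base import BaseEstimator

from homppi.blast_io import AlignmentRecord, compute_stats
from homppi.ic_model import InterfaceConservationRegressor, rank_templates
from homppi.structure_interface import LabelTrack, filter_template
from homppi.zoning import NPS_ZONES, Zone, ZoneThresholds, classify_nps

__all__ = [
    "TemplateChain",
    "Query",
    "Prediction",
    "NPSInterfacePredictor",
    "filter_homologs",
    "predict_nps",
    "vote_transfer",
]

VOTE_THRESHOLD = 0.5


@dataclass(frozen=True)
class TemplateChain:
    """A template sequence with metadata and an interface-label track.

    ``partner_id`` is None for the non-partner-specific union track and a
    chain id for partner-specific labels; ``complex_id`` names the solved
    complex the chain belongs to.
    """

    template_id: str
    sequence: str
    labels: LabelTrack
    species: str = ""
    method: str = "xray"
    resolution: Optional[float] = None
    complex_id: Optional[str] = None
    partner_id: Optional[str] = None

    def __post_init__(self):
        if len(self.labels) != len(self.sequence):
            raise ValueError(
                f"{self.template_id}: label track length {len(self.labels)} "
                f"!= sequence length {len(self.sequence)}")


@dataclass(frozen=True)
class Query:
    query_id: str
    sequence: str
    species: str = ""
    records: tuple[AlignmentRecord, ...] = ()


@dataclass
class Prediction:
    """Per-residue vote scores and interface calls for one query.

    ``scores[i]`` is None where no template cast a vote; such positions are
    called 0 but remain distinguishable via ``n_votes``.  ``predicted`` is
    False when no zone had any usable template (a not-predicted query,
    distinct from an all-zero prediction).
    """

    query_id: str
    scores: list[Optional[float]]
    calls: list[int]
    n_votes: list[int]
    zone_used: Optional[Zone]
    templates_used: list[str] = field(default_factory=list)
    predicted: bool = True

    @classmethod
    def not_predicted(cls, query_id: str, length: int) -> "Prediction":
        return cls(query_id=query_id, scores=[None] * length, calls=[0] * length,
                   n_votes=[0] * length, zone_used=None, templates_used=[],
                   predicted=False)

    def as_track(self) -> LabelTrack:
        return LabelTrack("".join(str(c) for c in self.calls))


def filter_homologs(
    query: Query,
    hits: Sequence[tuple[TemplateChain, AlignmentRecord]],
    identity_cutoff: float = 95.0,
) -> tuple[list[tuple[TemplateChain, AlignmentRecord]], list[tuple[str, str]]]:
    """Remove templates that would bias or degrade the transfer.

    Dropped: exact self-hits; hits with identity >= 95% *and* the query's
    species (the rule is a conjunction -- a 97%-identical template from a
    different species is kept); templates failing the structure-quality
    rule (non-X-ray, resolution > 3.5 A, < 3 interface residues).  Returns
    the kept hits and a removal log of (template_id, reason).
    """
    kept, removed = [], []
    for template, rec in hits:
        if template.sequence == query.sequence:
            removed.append((template.template_id, "self"))
            continue
        identity = 100.0 * rec.n_identical / rec.lal
        if identity >= identity_cutoff and template.species and \
                template.species == query.species:
            removed.append((template.template_id, "identity_species"))
            continue
        keep, reason = filter_template_chain(template)
        if not keep:
            removed.append((template.template_id, reason))
            continue
        kept.append((template, rec))
    return kept, removed


def filter_template_chain(template: TemplateChain) -> tuple[bool, Optional[str]]:
    """Structure-quality rule applied to a TemplateChain's metadata/labels."""
    class _Shim:
        method = template.method
        resolution = template.resolution
    return filter_template(_Shim(), template.labels)


def vote_transfer(
    query_len: int,
    ranked: Sequence[tuple[TemplateChain, AlignmentRecord]],
) -> tuple[list[Optional[float]], list[int], list[int]]:
    """Majority vote of template labels projected through the alignments.

    Each template votes at every query position its alignment covers with a
    non-gap column on both sides: +1 if the aligned template residue is an
    interface residue, -1 if not, abstain on '?'.
    """
    pos_votes = [0] * query_len
    neg_votes = [0] * query_len
    for template, rec in ranked:
        qpos, tpos = rec.q_start, rec.t_start
        for qc, tc in zip(rec.q_aln, rec.t_aln):
            q_here, t_here = qc != "-", tc != "-"
            if q_here and t_here and 1 <= tpos <= len(template.labels):
                label = template.labels[tpos - 1]
                if label == "1":
                    pos_votes[qpos - 1] += 1
                elif label == "0":
                    neg_votes[qpos - 1] += 1
            if q_here:
                qpos += 1
            if t_here:
                tpos += 1
    scores: list[Optional[float]] = []
    calls: list[int] = []
    n_votes: list[int] = []
    for p, n in zip(pos_votes, neg_votes):
        total = p + n
        n_votes.append(total)
        if total == 0:
            scores.append(None)
            calls.append(0)
        else:
            s = p / total
            scores.append(s)
            calls.append(1 if s >= VOTE_THRESHOLD else 0)
    return scores, calls, n_votes


def _dedupe_hsps(zone_hits, model):
    """One HSP per template: keep the best predicted IC (then lowest EVal)."""
    best = {}
    for template, rec, stats in zone_hits:
        ic = model.predict_one(stats)
        key = template.template_id
        if key not in best or (-ic, rec.eval) < (-best[key][0], best[key][2].eval):
            best[key] = (ic, template, rec, stats)
    return [(t, r, s) for _, t, r, s in
            sorted(best.values(), key=lambda item: item[1].template_id)]


def predict_nps(
    query: Query,
    hits: Sequence[tuple[TemplateChain, AlignmentRecord]],
    model: Optional[InterfaceConservationRegressor] = None,
    zones: tuple[ZoneThresholds, ...] = NPS_ZONES,
    k: int = 10,
) -> Prediction:
    """NPS interface prediction for one query from zone-filtered hits.

    ``hits`` should already have passed :func:`filter_homologs`.  Queries
    with no hit in any zone yield a not-predicted result.
    """
    model = model or InterfaceConservationRegressor(kind="nps")
    length = len(query.sequence)
    if not hits:
        return Prediction.not_predicted(query.query_id, length)

    by_zone: dict[Zone, list] = {}
    for template, rec in hits:
        stats = compute_stats(rec)
        zone = classify_nps(stats, zones)
        if zone is not None:
            by_zone.setdefault(zone, []).append((template, rec, stats))

    for zone in (Zone.SAFE, Zone.TWILIGHT1, Zone.TWILIGHT2, Zone.DARK):
        if zone in by_zone:
            candidates = _dedupe_hsps(by_zone[zone], model)
            ranked = rank_templates(
                [(t, s) for t, _, s in candidates], model, k=k)
            chosen_ids = [t.template_id for t, _ in ranked]
            chosen = [(t, r) for t, r, _ in candidates if t.template_id in chosen_ids]
            # preserve the rank order
            order = {tid: i for i, tid in enumerate(chosen_ids)}
            chosen.sort(key=lambda tr: order[tr[0].template_id])
            scores, calls, n_votes = vote_transfer(length, chosen)
            return Prediction(query_id=query.query_id, scores=scores, calls=calls,
                              n_votes=n_votes, zone_used=zone,
                              templates_used=chosen_ids, predicted=True)
    return Prediction.not_predicted(query.query_id, length)


class NPSInterfacePredictor(BaseEstimator):
    """Scikit-learn-style wrapper around the NPS transfer algorithm.

    ``fit`` registers the template library (chains with interface labels);
    ``predict`` maps each query -- carrying its own BLAST records -- to a
    :class:`Prediction`.

    Parameters
    ----------
    k : int
        Maximum number of templates consulted per query.
    zones : tuple of ZoneThresholds
        Homology-zone boundary table.
    model : InterfaceConservationRegressor, optional
        Ranking model; the published default NPS coefficients when omitted.
    apply_filters : bool
        Apply the homolog-removal rules inside ``predict``.
    """

    def __init__(self, k: int = 10, zones: tuple[ZoneThresholds, ...] = NPS_ZONES,
                 model: Optional[InterfaceConservationRegressor] = None,
                 apply_filters: bool = True):
        self.k = k
        self.zones = zones
        self.model = model
        self.apply_filters = apply_filters

    def fit(self, templates: Sequence[TemplateChain], y=None) -> "NPSInterfacePredictor":
        self.templates_ = {}
        for t in templates:
            if t.partner_id is None:  # NPS consumes union tracks only
                self.templates_[t.template_id] = t
        return self

    def predict(self, queries: Sequence[Query]) -> list[Prediction]:
        if not hasattr(self, "templates_"):
            raise RuntimeError("predictor is not fitted; call fit(templates) first")
        model = self.model or InterfaceConservationRegressor(kind="nps")
        out = []
        for query in queries:
            hits = [(self.templates_[r.template_id], r) for r in query.records
                    if r.template_id in self.templates_]
            if self.apply_filters:
                hits, _ = filter_homologs(query, hits)
            out.append(predict_nps(query, hits, model=model,
                                   zones=self.zones, k=self.k))
        return out
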