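"""Synthetic fixtures: toy complexes, homolog families, PS scenarios.

Everything here is generated, seed-deterministic and analytically labelled,
so the whole pipeline is testable offline:

* :func:`make_complex` builds pseudo-atom chains with a designated contact
  patch whose interface labels are known by construction;
* :func:`mutate_homolog` derives a homolog of a labelled chain at a chosen
  divergence, together with the ground-truth pairwise alignment and a
  fabricated BLAST-style record;
* :func:`make_ps_scenario` builds a query A with two distinct
  partner-specific interfaces (one used with partner B, one with a decoy
  partner C) plus the homo-interolog templates and complex index needed to
  exercise the PS predictor.

Synthetic expectation values follow eval = exp(ln(Lq*Lt) - lambda*nident)
with lambda = 2.0 (exponent clamped at -450): a decreasing function of the
number of identical residues chosen only so fixtures land in the intended
homology zones, with no claim to Karlin-Altschul fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from Bio.Align import substitution_matrices

from homppi.blast_io import AlignmentRecord
from homppi.nps_predictor import Query, TemplateChain
from homppi.ps_predictor import ComplexIndex
from homppi.structure_interface import Atom, ChainStructure, LabelTrack, Residue

__all__ = ["make_complex", "mutate_homolog", "make_ps_scenario",
           "PSScenario", "synthetic_eval"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Residue spacing along the chain axis, A.  Chosen so that residues
#: adjacent to a contact patch stay > 6 A from the partner chain while
#: patch pairs sit at 3.2-3.8 A.
RESIDUE_SPACING = 5.0
CHAIN_SEPARATION = 10.0
EVAL_LAMBDA = 2.0


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def synthetic_eval(query_len: int, template_len: int, n_identical: int) -> float:
    """Fabricated BLAST expectation value (see module docstring)."""
    exponent = max(math.log(query_len * template_len) - EVAL_LAMBDA * n_identical,
                   -450.0)
    return math.exp(exponent)


def make_complex(
    n_chains: int = 2,
    len_range: tuple[int, int] = (30, 60),
    contact_patch_size: int = 4,
    seed: int = 0,
    missing_rate: float = 0.0,
    resolution: float = 2.0,
) -> tuple[list[ChainStructure], dict[str, LabelTrack],
           dict[tuple[str, str], LabelTrack]]:
    """Toy complex with analytically known contacts.

    Chains are straight pseudo-atom paths (one CA plus one side-chain
    pseudo-atom per residue) stacked 10 A apart; for each adjacent chain
    pair a shared patch of ``contact_patch_size`` residue indices on the
    upper chain is lowered to 3.2-3.8 A from the lower chain.  All other
    inter-chain residue pairs are > 6 A apart and every residue is solvent
    exposed, so the interface labels are exactly the patch indices.

    Returns ``(chains, union_tracks, ps_tracks)`` where ``ps_tracks`` is
    keyed by (chain_id, partner_id).  With ``missing_rate`` > 0, randomly
    chosen non-patch residues are left unresolved and labelled ``?``.
    """
    if n_chains < 2:
        raise ValueError("a complex needs at least two chains")
    rng = np.random.default_rng(seed)
    lengths = [int(rng.integers(len_range[0], len_range[1] + 1))
               for _ in range(n_chains)]
    sequences = [_random_sequence(rng, L) for L in lengths]
    chain_ids = [chr(ord("A") + j) for j in range(n_chains)]

    # one shared patch index range per adjacent pair, disjoint on each chain
    used: dict[int, set[int]] = {j: set() for j in range(n_chains)}
    patches: list[range] = []
    for j in range(n_chains - 1):
        limit = min(lengths[j], lengths[j + 1]) - contact_patch_size
        if limit < 0:
            raise ValueError("chains too short for the requested patch size")
        for _ in range(200):
            start = int(rng.integers(0, limit + 1)) if limit > 0 else 0
            span = set(range(start, start + contact_patch_size))
            if not (span & used[j]) and not (span & used[j + 1]):
                break
        else:
            raise ValueError("could not place disjoint contact patches")
        used[j].update(span)
        used[j + 1].update(span)
        patches.append(range(start, start + contact_patch_size))

    # geometry: chain j along x at y = j*10; patch residues of chain j+1
    # lowered to y_j + gap, gap ~ U(3.2, 3.8)
    y_base = [j * CHAIN_SEPARATION for j in range(n_chains)]
    y_coord = [[y_base[j]] * lengths[j] for j in range(n_chains)]
    for j, patch in enumerate(patches):
        for i in patch:
            y_coord[j + 1][i] = y_base[j] + float(rng.uniform(3.2, 3.8))

    chains = []
    for j in range(n_chains):
        residues = []
        for i in range(lengths[j]):
            in_patch = i in used[j]
            resolved = in_patch or missing_rate <= 0 or rng.random() >= missing_rate
            x = RESIDUE_SPACING * i
            atoms = [Atom("C", x, y_coord[j][i], 0.0, name="CA"),
                     Atom("C", x, y_coord[j][i], 1.5, name="CB")] if resolved else []
            residues.append(Residue(seq_index=i + 1,
                                    residue_type=sequences[j][i],
                                    atoms=atoms, resolved=resolved))
        chain = ChainStructure(chain_id=chain_ids[j], residues=residues,
                               full_sequence=sequences[j], method="xray",
                               resolution=resolution)
        chain.validate()
        chains.append(chain)

    ps_tracks: dict[tuple[str, str], LabelTrack] = {}
    for j, patch in enumerate(patches):
        for side, other in ((j, j + 1), (j + 1, j)):
            labels = []
            for i in range(lengths[side]):
                if not chains[side].residues[i].resolved:
                    labels.append("?")
                else:
                    labels.append("1" if i in patch else "0")
            ps_tracks[(chain_ids[side], chain_ids[other])] = LabelTrack("".join(labels))

    union_tracks: dict[str, LabelTrack] = {}
    for j, cid in enumerate(chain_ids):
        partner_tracks = [t for (c, _), t in ps_tracks.items() if c == cid]
        track = partner_tracks[0]
        for extra in partner_tracks[1:]:
            track = track.union(extra)
        union_tracks[cid] = track
    return chains, union_tracks, ps_tracks


@dataclass(frozen=True)
class HomologResult:
    sequence: str
    labels: LabelTrack
    q_aln: str
    t_aln: str
    record: AlignmentRecord


def mutate_homolog(
    sequence: str,
    labels: LabelTrack,
    sub_rate: float = 0.1,
    indel_rate: float = 0.0,
    interface_conservation_bias: float = 0.0,
    interface_loss_on_sub: float = 0.5,
    seed: int = 0,
    query_id: str = "query",
    template_id: str = "tmpl",
) -> HomologResult:
    """Derive a homolog of a labelled chain at controlled divergence.

    Point substitutions hit non-interface positions at ``sub_rate`` and
    interface positions at ``sub_rate * (1 - bias)``, so bias = 1 freezes
    the interface.  Short indels (1-3 residues) occur at ``indel_rate`` per
    position.  Aligned homolog positions inherit the original's label,
    except that a *substituted* interface residue loses its interface
    status with probability ``interface_loss_on_sub`` -- interface
    conservation in the homolog therefore degrades with sequence
    divergence, as it does in real families.  Inserted residues are
    non-interface.  The exact alignment is returned together with a
    BLAST-style record whose statistics (eval, identity, positives, LAL)
    are computed from that alignment.
    """
    if len(labels) != len(sequence):
        raise ValueError("labels and sequence must have equal length")
    rng = np.random.default_rng(seed)
    q_aln: list[str] = []
    t_aln: list[str] = []
    hom_seq: list[str] = []
    hom_labels: list[str] = []
    for i, aa in enumerate(sequence):
        if indel_rate > 0 and rng.random() < indel_rate / 2.0:
            # deletion in the homolog
            q_aln.append(aa)
            t_aln.append("-")
            continue
        rate = sub_rate * (1.0 - interface_conservation_bias) \
            if labels[i] == "1" else sub_rate
        label = labels[i]
        if rng.random() < rate:
            choices = [c for c in AMINO_ACIDS if c != aa]
            new = str(rng.choice(choices))
            if label == "1" and rng.random() < interface_loss_on_sub:
                label = "0"
        else:
            new = aa
        q_aln.append(aa)
        t_aln.append(new)
        hom_seq.append(new)
        hom_labels.append(label)
        if indel_rate > 0 and rng.random() < indel_rate / 2.0:
            ins_len = int(rng.integers(1, 4))
            for _ in range(ins_len):
                ins = str(rng.choice(list(AMINO_ACIDS)))
                q_aln.append("-")
                t_aln.append(ins)
                hom_seq.append(ins)
                hom_labels.append("0")
    q_str, t_str = "".join(q_aln), "".join(t_aln)
    n_identical = sum(1 for a, b in zip(q_str, t_str) if a == b and a != "-")
    n_positive = n_identical + sum(
        1 for a, b in zip(q_str, t_str)
        if a != "-" and b != "-" and a != b and _BLOSUM62[a][b] > 0)
    homolog = "".join(hom_seq)
    record = AlignmentRecord(
        query_id=query_id, template_id=template_id,
        eval=synthetic_eval(len(sequence), len(homolog), n_identical),
        n_identical=n_identical, n_positive=n_positive, lal=len(q_str),
        query_len=len(sequence), template_len=len(homolog),
        q_aln=q_str, t_aln=t_str,
        q_start=1, q_end=len(sequence), t_start=1, t_end=len(homolog),
    )
    record.validate()
    return HomologResult(sequence=homolog, labels=LabelTrack("".join(hom_labels)),
                         q_aln=q_str, t_aln=t_str, record=record)


@dataclass
class PSScenario:
    """A query A with two partner-specific interfaces and the templates to find them."""

    query_a: Query
    query_b: Query
    query_c: Query
    templates: list[TemplateChain]
    complex_index: ComplexIndex
    truth_a_with_b: LabelTrack
    truth_a_with_c: LabelTrack
    truth_union_a: LabelTrack

    def validate(self) -> None:
        assert self.truth_a_with_b.labels != self.truth_a_with_c.labels, \
            "partner-specific truths must differ"
        assert self.truth_union_a.n_interface == (
            self.truth_a_with_b.n_interface + self.truth_a_with_c.n_interface), \
            "union must be the disjoint union of the two PS interfaces"
        for t in self.templates:
            assert len(t.labels) == len(t.sequence)


def _patch_track(length: int, patch: range) -> LabelTrack:
    return LabelTrack("".join("1" if i in patch else "0" for i in range(length)))


def make_ps_scenario(seed: int = 0, length_a: int = 120,
                     sub_rate: float = 0.05) -> PSScenario:
    """Two-partner fixture for the partner-specificity property.

    Query A carries two disjoint interface patches: one used with partner B
    (complex CPX1, through homo-interolog A1'-B1') and one with a decoy
    partner C (complex CPX2, through A2'-C1').  PS labels of the A
    homologs differ by partner while each template also carries its union
    track, so PS and NPS predictions can be compared on the same library.
    """
    rng = np.random.default_rng(seed)
    seq_a = _random_sequence(rng, length_a)
    seq_b = _random_sequence(rng, int(rng.integers(90, 130)))
    seq_c = _random_sequence(rng, int(rng.integers(90, 130)))

    patch_size = 8
    start_b = int(rng.integers(0, length_a // 2 - patch_size))
    start_c = int(rng.integers(length_a // 2, length_a - patch_size))
    patch_ab = range(start_b, start_b + patch_size)
    patch_ac = range(start_c, start_c + patch_size)

    truth_ab = _patch_track(length_a, patch_ab)
    truth_ac = _patch_track(length_a, patch_ac)
    truth_b = _patch_track(len(seq_b), range(5, 5 + patch_size))
    truth_c = _patch_track(len(seq_c), range(5, 5 + patch_size))

    sub_seeds = rng.integers(0, 2**31 - 1, size=4)
    hom_a1 = mutate_homolog(seq_a, truth_ab, sub_rate=sub_rate, seed=int(sub_seeds[0]),
                            query_id="A", template_id="A1p")
    hom_a2 = mutate_homolog(seq_a, truth_ac, sub_rate=sub_rate, seed=int(sub_seeds[1]),
                            query_id="A", template_id="A2p")
    hom_b1 = mutate_homolog(seq_b, truth_b, sub_rate=sub_rate, seed=int(sub_seeds[2]),
                            query_id="B", template_id="B1p")
    hom_c1 = mutate_homolog(seq_c, truth_c, sub_rate=sub_rate, seed=int(sub_seeds[3]),
                            query_id="C", template_id="C1p")

    union_a1 = hom_a1.labels.union(_project(truth_ac, hom_a1))  # both patches
    templates = [
        # partner-specific tracks
        TemplateChain("A1p", hom_a1.sequence, hom_a1.labels, species="sp_x",
                      resolution=2.0, complex_id="CPX1", partner_id="B1p"),
        TemplateChain("B1p", hom_b1.sequence, hom_b1.labels, species="sp_x",
                      resolution=2.0, complex_id="CPX1", partner_id="A1p"),
        TemplateChain("A2p", hom_a2.sequence, hom_a2.labels, species="sp_y",
                      resolution=2.0, complex_id="CPX2", partner_id="C1p"),
        TemplateChain("C1p", hom_c1.sequence, hom_c1.labels, species="sp_y",
                      resolution=2.0, complex_id="CPX2", partner_id="A2p"),
        # union tracks for NPS (A homologs carry both patches' union where aligned)
        TemplateChain("A1p", hom_a1.sequence, union_a1, species="sp_x",
                      resolution=2.0, complex_id="CPX1", partner_id=None),
        TemplateChain("B1p", hom_b1.sequence, hom_b1.labels, species="sp_x",
                      resolution=2.0, complex_id="CPX1", partner_id=None),
        TemplateChain("C1p", hom_c1.sequence, hom_c1.labels, species="sp_y",
                      resolution=2.0, complex_id="CPX2", partner_id=None),
    ]
    index = ComplexIndex()
    index.add_interaction("CPX1", "A1p", "B1p")
    index.add_interaction("CPX2", "A2p", "C1p")

    query_a = Query("A", seq_a, species="sp_query",
                    records=(hom_a1.record, hom_a2.record))
    query_b = Query("B", seq_b, species="sp_query", records=(hom_b1.record,))
    query_c = Query("C", seq_c, species="sp_query", records=(hom_c1.record,))

    scenario = PSScenario(query_a=query_a, query_b=query_b, query_c=query_c,
                          templates=templates, complex_index=index,
                          truth_a_with_b=truth_ab, truth_a_with_c=truth_ac,
                          truth_union_a=truth_ab.union(truth_ac))
    scenario.validate()
    return scenario


def _project(query_track: LabelTrack, hom: HomologResult) -> LabelTrack:
    """Project a query-coordinate track onto a homolog through its alignment."""
    out = ["0"] * len(hom.sequence)
    qpos = tpos = 0
    for qc, tc in zip(hom.q_aln, hom.t_aln):
        if qc != "-" and tc != "-":
            out[tpos] = query_track[qpos]
        if qc != "-":
            qpos += 1
        if tc != "-":
            tpos += 1
    return LabelTrack("".join(out))
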