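"""Gold-standard interface labels from multi-chain structures.

A residue is *surface* when its relative solvent-accessible area (RASA),
computed on the isolated chain, is at least 5% of the residue-type maximum;
it is an *interface* residue when it is surface and has any atom within
4 Angstrom of any atom of a partner chain.  Labels live on full-sequence
coordinates: ``1`` interface, ``0`` non-interface, ``?`` where coordinates
are missing.

SASA uses deterministic Shrake-Rupley sphere sampling with a golden-spiral
point lattice; RASA divides by the theoretical Gly-X-Gly maxima of Tien et
al. (2013).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "ChainStructure",
    "LabelTrack",
    "MAX_ASA",
    "VDW_RADII",
    "shrake_rupley_sasa",
    "relative_asa",
    "label_interfaces",
    "filter_template",
    "read_pdb_chains",
    "write_pdb",
]

#: Theoretical maximum ASA per residue type (Gly-X-Gly, Tien et al. 2013), A^2.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
#: Fallback maximum for unknown residue types (median of the table).
FALLBACK_MAX_ASA = 197.0

#: Van der Waals radii by element, A.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.80

_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}
_1TO3 = {v: k for k, v in _3TO1.items() if k != "MSE"}


@dataclass(frozen=True)
class Atom:
    element: str
    x: float
    y: float
    z: float
    name: str = ""


@dataclass
class Residue:
    seq_index: int  # 1-based position on full_sequence
    residue_type: str  # one-letter code
    atoms: list[Atom] = field(default_factory=list)
    resolved: bool = True


@dataclass
class ChainStructure:
    """One chain of a structure with its full sequence and resolved residues."""

    chain_id: str
    residues: list[Residue]
    full_sequence: str
    method: str = "xray"  # xray | nmr | other
    resolution: Optional[float] = None

    def validate(self) -> None:
        prev = 0
        for res in self.residues:
            if res.seq_index <= prev:
                raise ValueError(f"chain {self.chain_id}: seq_index not strictly increasing")
            prev = res.seq_index
            if res.seq_index > len(self.full_sequence):
                raise ValueError(f"chain {self.chain_id}: seq_index {res.seq_index} "
                                 f"beyond sequence length {len(self.full_sequence)}")
            if res.resolved and not res.atoms:
                raise ValueError(f"chain {self.chain_id}: resolved residue "
                                 f"{res.seq_index} has no atoms")
            if res.resolved and res.residue_type != self.full_sequence[res.seq_index - 1]:
                raise ValueError(
                    f"chain {self.chain_id}: residue {res.seq_index} type "
                    f"{res.residue_type} != sequence {self.full_sequence[res.seq_index - 1]}")

    def resolved_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.resolved and r.atoms]

    def atom_array(self) -> tuple[np.ndarray, np.ndarray, list[int]]:
        """(coords, vdw radii, residue index per atom) over resolved residues."""
        coords, radii, owner = [], [], []
        for i, res in enumerate(self.resolved_residues()):
            for atom in res.atoms:
                coords.append((atom.x, atom.y, atom.z))
                radii.append(VDW_RADII.get(atom.element.upper(), DEFAULT_VDW))
                owner.append(i)
        if not coords:
            return np.empty((0, 3)), np.empty(0), []
        return np.asarray(coords), np.asarray(radii), owner


@dataclass(frozen=True)
class LabelTrack:
    """Per-position interface labels over a full sequence: '0', '1' or '?'."""

    labels: str

    def __post_init__(self):
        bad = set(self.labels) - {"0", "1", "?"}
        if bad:
            raise ValueError(f"invalid label characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    @property
    def n_interface(self) -> int:
        return self.labels.count("1")

    def union(self, other: "LabelTrack") -> "LabelTrack":
        """Positionwise union: 1 dominates, then 0, then '?'."""
        if len(other) != len(self):
            raise ValueError("cannot union tracks of different lengths")
        out = []
        for a, b in zip(self.labels, other.labels):
            if "1" in (a, b):
                out.append("1")
            elif "0" in (a, b):
                out.append("0")
            else:
                out.append("?")
        return LabelTrack("".join(out))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = 1.4, n_points: int = 256) -> np.ndarray:
    """Per-atom solvent-accessible surface area, A^2.

    Each atom's solvent sphere (radius vdw + probe) is sampled on a fixed
    point lattice; a point is accessible when it lies outside every other
    atom's solvent sphere.  Deterministic for fixed ``n_points``.
    """
    n = len(coords)
    if n == 0:
        return np.empty(0)
    unit = _sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    out = np.zeros(n)
    max_ext = ext.max()
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                      if j != i]
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 > (ext[nb] ** 2)[None, :], axis=1)
        else:
            accessible = np.ones(len(pts), dtype=bool)
        out[i] = 4.0 * math.pi * ext[i] ** 2 * accessible.mean()
    return out


def relative_asa(chain: ChainStructure, probe: float = 1.4,
                 n_points: int = 256) -> dict[int, float]:
    """RASA per resolved residue (keyed by seq_index), on the isolated chain.

    RASA is the residue's summed atom SASA divided by the residue type's
    Gly-X-Gly maximum; exposed termini may slightly exceed 1.
    """
    residues = chain.resolved_residues()
    coords, radii, owner = chain.atom_array()
    if len(coords) == 0:
        return {}
    sasa = shrake_rupley_sasa(coords, radii, probe=probe, n_points=n_points)
    per_res = np.zeros(len(residues))
    for atom_i, res_i in enumerate(owner):
        per_res[res_i] += sasa[atom_i]
    out = {}
    for res, area in zip(residues, per_res):
        ref = MAX_ASA.get(res.residue_type)
        if ref is None:
            warnings.warn(f"unknown residue type {res.residue_type!r}; "
                          f"using fallback max ASA {FALLBACK_MAX_ASA}")
            ref = FALLBACK_MAX_ASA
        out[res.seq_index] = area / ref
    return out


def label_interfaces(chains: Sequence[ChainStructure],
                     partner_ids: Optional[dict[str, set[str]]] = None,
                     dist_cutoff: float = 4.0,
                     rasa_cutoff: float = 0.05,
                     n_points: int = 256) -> dict[str, LabelTrack]:
    """Interface label track per chain.

    A residue is labelled ``1`` iff its RASA (isolated chain) is at least
    ``rasa_cutoff`` and any of its atoms lies within ``dist_cutoff`` of any
    atom of a partner chain.  With ``partner_ids`` omitted every other
    chain is a partner (the NPS union); passing ``{chain_id: {...}}``
    restricts contacts to the named partners (PS labels).  Unresolved
    positions are ``?``.
    """
    if len(chains) < 2:
        raise ValueError("interface labelling needs at least two chains")
    by_id = {c.chain_id: c for c in chains}
    arrays = {c.chain_id: c.atom_array() for c in chains}
    trees = {cid: cKDTree(coords) if len(coords) else None
             for cid, (coords, _, _) in arrays.items()}

    tracks: dict[str, LabelTrack] = {}
    for chain in chains:
        partners = (partner_ids.get(chain.chain_id, set()) if partner_ids is not None
                    else set(by_id) - {chain.chain_id})
        partners = {p for p in partners if p in by_id and p != chain.chain_id}
        if not partners:
            raise ValueError(f"chain {chain.chain_id} has no partner chain to label against")
        rasa = relative_asa(chain, n_points=n_points)
        residues = chain.resolved_residues()
        coords, _, owner = arrays[chain.chain_id]
        # min distance from any atom of each residue to any partner atom
        min_d = np.full(len(residues), np.inf)
        for pid in sorted(partners):
            tree = trees[pid]
            if tree is None:
                continue
            d, _ = tree.query(coords)
            for atom_i, res_i in enumerate(owner):
                if d[atom_i] < min_d[res_i]:
                    min_d[res_i] = d[atom_i]
        labels = ["?"] * len(chain.full_sequence)
        for res, dist in zip(residues, min_d):
            contact = dist <= dist_cutoff
            surface = rasa.get(res.seq_index, 0.0) >= rasa_cutoff
            labels[res.seq_index - 1] = "1" if (contact and surface) else "0"
        tracks[chain.chain_id] = LabelTrack("".join(labels))
    return tracks


def filter_template(chain: ChainStructure,
                    track: LabelTrack,
                    max_resolution: float = 3.5,
                    min_interface: int = 3) -> tuple[bool, Optional[str]]:
    """Template retention rule: X-ray, resolution <= 3.5 A, >= 3 interface residues.

    Returns ``(keep, reason)``; ``reason`` names the first rule that fired.
    """
    if chain.method != "xray":
        return False, "method"
    if chain.resolution is None or chain.resolution > max_resolution:
        return False, "resolution"
    if track.n_interface < min_interface:
        return False, "interface_count"
    return True, None


# ---------------------------------------------------------------------------
# PDB input / output


def _method_tag(raw: Optional[str]) -> str:
    raw = (raw or "").lower()
    if "x-ray" in raw or "xray" in raw:
        return "xray"
    if "nmr" in raw:
        return "nmr"
    return "other"


def read_pdb_chains(path, full_sequences: Optional[dict[str, str]] = None
                    ) -> list[ChainStructure]:
    """Read MODEL 1 of a PDB file into chain structures.

    Only standard amino-acid residues are kept (HETATM-only entities are
    ignored).  The full sequence per chain comes from, in order of
    preference: the ``full_sequences`` argument, SEQRES records, or the
    ATOM-derived sequence.  When residue numbering disagrees with the full
    sequence, the ATOM residues are re-anchored by pairwise alignment.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    header = structure.header or {}
    method = _method_tag(header.get("structure_method"))
    resolution = header.get("resolution")

    seqres = _read_seqres(path)
    model = next(iter(structure))
    chains = []
    for chain in model:
        residues = []
        for res in chain:
            hetflag, resseq, _ = res.id
            if hetflag.strip():
                continue
            one = _3TO1.get(res.get_resname().upper())
            if one is None:
                continue
            atoms = [Atom(element=(a.element or a.get_name()[0]).strip().upper(),
                          x=float(a.coord[0]), y=float(a.coord[1]),
                          z=float(a.coord[2]), name=a.get_name())
                     for a in res]
            residues.append(Residue(seq_index=resseq, residue_type=one, atoms=atoms))
        if not residues:
            continue
        atom_seq = "".join(r.residue_type for r in residues)
        full = None
        if full_sequences and chain.id in full_sequences:
            full = full_sequences[chain.id]
        elif chain.id in seqres:
            full = seqres[chain.id]
        if full is None:
            # no reference sequence: renumber consecutively from 1
            for i, r in enumerate(residues, start=1):
                r.seq_index = i
            full = atom_seq
        elif not _numbering_consistent(residues, full):
            _anchor_by_alignment(residues, atom_seq, full)
        cs = ChainStructure(chain_id=chain.id, residues=residues,
                            full_sequence=full, method=method,
                            resolution=resolution)
        cs.validate()
        chains.append(cs)
    return chains


def _numbering_consistent(residues: list[Residue], full: str) -> bool:
    return all(1 <= r.seq_index <= len(full)
               and full[r.seq_index - 1] == r.residue_type for r in residues)


def _anchor_by_alignment(residues: list[Residue], atom_seq: str, full: str) -> None:
    """Re-assign seq_index by locally aligning the ATOM sequence to the full one."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aln = aligner.align(full, atom_seq)[0]
    mapping: dict[int, int] = {}
    for (f_start, f_end), (a_start, a_end) in zip(*aln.aligned):
        for offset in range(f_end - f_start):
            mapping[a_start + offset] = f_start + offset + 1
    for i, res in enumerate(residues):
        if i in mapping:
            res.seq_index = mapping[i]
        else:
            res.resolved = False
    residues[:] = [r for r in residues if r.resolved]


def _read_seqres(path) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("SEQRES"):
                chain_id = line[11].strip()
                for name in line[19:].split():
                    out.setdefault(chain_id, []).append(_3TO1.get(name.upper(), "X"))
    return {cid: "".join(seq) for cid, seq in out.items()}


def write_pdb(chains: Sequence[ChainStructure], stream: TextIO) -> None:
    """Write chains as minimal PDB text (SEQRES + ATOM records, MODEL 1)."""
    for chain in chains:
        seq3 = [_1TO3.get(aa, "UNK") for aa in chain.full_sequence]
        for row_i in range(0, len(seq3), 13):
            row = seq3[row_i:row_i + 13]
            stream.write(f"SEQRES {row_i // 13 + 1:3d} {chain.chain_id}"
                         f" {len(seq3):4d}  " + " ".join(row) + "\n")
    stream.write("MODEL        1\n")
    serial = 1
    for chain in chains:
        for res in chain.resolved_residues():
            res3 = _1TO3.get(res.residue_type, "UNK")
            for atom in res.atoms:
                name = (atom.name or atom.element).ljust(3)
                stream.write(
                    f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} {chain.chain_id}"
                    f"{res.seq_index:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"  1.00  0.00          {atom.element:>2s}\n")
                serial += 1
        stream.write("TER\n")
    stream.write("ENDMDL\nEND\n")
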