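"""Solvent accessibility, structure-derived interface labels, template filtering."""

import io
import itertools

import numpy as np
import pytest

from homppi.simulate import make_complex
from homppi.structure_interface import (
    Atom,
    ChainStructure,
    LabelTrack,
    Residue,
    filter_template,
    label_interfaces,
    read_pdb_chains,
    relative_asa,
    shrake_rupley_sasa,
    write_pdb,
)


def single_residue_chain(aa="A", chain_id="A", xyz=(0.0, 0.0, 0.0)):
    return ChainStructure(
        chain_id=chain_id,
        residues=[Residue(1, aa, [Atom("C", *xyz, name="CA")])],
        full_sequence=aa, method="xray", resolution=2.0)


def brute_force_labels(chains, dist_cutoff=4.0, rasa_cutoff=0.05):
    """Independent O(n^2) oracle: all-pairs atom distances, no spatial index."""
    out = {}
    for chain in chains:
        rasa = relative_asa(chain)
        labels = ["?"] * len(chain.full_sequence)
        for res in chain.resolved_residues():
            contact = False
            for other in chains:
                if other.chain_id == chain.chain_id:
                    continue
                for ores in other.resolved_residues():
                    for a, b in itertools.product(res.atoms, ores.atoms):
                        d = ((a.x - b.x) ** 2 + (a.y - b.y) ** 2
                             + (a.z - b.z) ** 2) ** 0.5
                        if d <= dist_cutoff:
                            contact = True
            surface = rasa.get(res.seq_index, 0.0) >= rasa_cutoff
            labels[res.seq_index - 1] = "1" if (contact and surface) else "0"
        out[chain.chain_id] = "".join(labels)
    return out


class TestRASA:
    def test_isolated_alanine_fully_exposed(self):
        # a lone residue: every sample point accessible, so RASA ~ atom
        # sphere area / reference -- near 1 within sampling tolerance
        chain = ChainStructure(
            chain_id="A",
            residues=[Residue(1, "G", [Atom("C", 0, 0, 0, name="CA")])],
            full_sequence="G", method="xray", resolution=2.0)
        rasa = relative_asa(chain)
        assert rasa[1] == pytest.approx(1.0, abs=0.2)

    def test_buried_residue_in_close_packed_cluster(self):
        # central atom caged by 26 neighbours on a 3 A lattice
        atoms = [Atom("C", 3.0 * dx, 3.0 * dy, 3.0 * dz)
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                 if (dx, dy, dz) != (0, 0, 0)]
        chain = ChainStructure(
            chain_id="A",
            residues=[Residue(1, "A", [Atom("C", 0, 0, 0, name="CA")]),
                      Residue(2, "A", atoms)],
            full_sequence="AA", method="xray", resolution=2.0)
        rasa = relative_asa(chain)
        assert rasa[1] < 0.05

    def test_empty_chain(self):
        chain = ChainStructure("A", [], "", method="xray", resolution=2.0)
        assert relative_asa(chain) == {}

    def test_unknown_residue_type_warns_and_falls_back(self):
        chain = ChainStructure(
            chain_id="A",
            residues=[Residue(1, "X", [Atom("C", 0, 0, 0)])],
            full_sequence="X", method="xray", resolution=2.0)
        with pytest.warns(UserWarning, match="unknown residue"):
            rasa = relative_asa(chain)
        assert rasa[1] > 0

    def test_matches_independent_shrake_rupley_implementation(self):
        # cross-check the sphere-sampling SASA against Biopython's
        from Bio.PDB.SASA import ShrakeRupley as BpShrakeRupley
        from Bio.PDB.StructureBuilder import StructureBuilder

        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 12, size=(20, 3))
        builder = StructureBuilder()
        builder.init_structure("s")
        builder.init_model(0)
        builder.init_chain("A")
        builder.init_seg(" ")
        for i, xyz in enumerate(coords):
            builder.init_residue("ALA", " ", i + 1, " ")
            builder.init_atom("CA", xyz.astype(np.float32), 0.0, 1.0, " ",
                              "CA", i, element="C")
        structure = builder.get_structure()
        BpShrakeRupley(probe_radius=1.4, n_points=960).compute(structure, level="A")
        reference = np.array([a.sasa for a in structure.get_atoms()])
        ours = shrake_rupley_sasa(coords, np.full(20, 1.70), n_points=960)
        np.testing.assert_allclose(ours, reference, rtol=0.06, atol=1.5)


class TestLabelInterfaces:
    def _pair(self, gap):
        """Two 5-residue chains, one aligned residue pair at the given gap."""
        def chain(cid, y_patch, patch_index):
            residues = []
            for i in range(5):
                y = y_patch if (i == patch_index and cid == "B") else (0.0 if cid == "A" else 20.0)
                residues.append(Residue(i + 1, "A", [Atom("C", 6.0 * i, y, 0.0)]))
            return ChainStructure(cid, residues, "AAAAA", method="xray", resolution=2.0)
        a = chain("A", None, None)
        b = chain("B", gap, 2)
        return [a, b]

    def test_single_contact_pair_labelled_on_both_chains(self):
        tracks = label_interfaces(self._pair(3.5))
        assert tracks["A"].labels == "00100"
        assert tracks["B"].labels == "00100"

    def test_gap_beyond_cutoff_gives_no_interface(self):
        tracks = label_interfaces(self._pair(4.5))
        assert tracks["A"].labels == "00000"
        assert tracks["B"].labels == "00000"

    def test_buried_contact_is_not_interface(self):
        chains = self._pair(3.5)
        # cage chain A's contacting residue (same-chain burial) so its RASA
        # drops below 5% while the inter-chain contact remains
        cage = [Atom("C", 12.0 + 3.0 * dx, 3.0 * dy, 3.0 * dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)]
        a = chains[0]
        chains[0] = ChainStructure(
            "A", a.residues + [Residue(6, "A", cage)], a.full_sequence + "A",
            method="xray", resolution=2.0)
        tracks = label_interfaces(chains)
        rasa = relative_asa(chains[0])
        assert rasa[3] < 0.05  # the precondition the fixture forces
        assert tracks["A"].labels[2] == "0"

    def test_needs_two_chains(self):
        with pytest.raises(ValueError):
            label_interfaces(self._pair(3.5)[:1])

    def test_unresolved_positions_marked_missing(self):
        chains, _, _ = make_complex(seed=11, missing_rate=0.3)
        tracks = label_interfaces(chains)
        for chain in chains:
            track = tracks[chain.chain_id]
            resolved = {r.seq_index for r in chain.resolved_residues()}
            for i, label in enumerate(track.labels, start=1):
                assert (label == "?") == (i not in resolved)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_fixture_complexes(self, seed):
        n_chains = 2 + seed % 2
        chains, union_tracks, _ = make_complex(
            n_chains=n_chains, seed=seed, len_range=(20, 35))
        tracks = label_interfaces(chains)
        oracle = brute_force_labels(chains)
        for cid in tracks:
            assert tracks[cid].labels == oracle[cid]
            assert tracks[cid].labels == union_tracks[cid].labels

    def test_monotone_in_distance_cutoff(self):
        chains, _, _ = make_complex(seed=5)
        small = label_interfaces(chains, dist_cutoff=3.5)
        large = label_interfaces(chains, dist_cutoff=6.5)
        for cid in small:
            for a, b in zip(small[cid].labels, large[cid].labels):
                if a == "1":
                    assert b == "1"

    def test_symmetry_of_contacts(self):
        chains, _, _ = make_complex(seed=9)
        tracks = label_interfaces(chains)
        assert (tracks["A"].n_interface > 0) == (tracks["B"].n_interface > 0)

    def test_partner_restriction(self):
        chains, _, ps_tracks = make_complex(n_chains=3, seed=4, len_range=(25, 40))
        only_ab = label_interfaces(
            chains[:2], partner_ids={"A": {"B"}, "B": {"A"}})
        assert only_ab["A"].labels == ps_tracks[("A", "B")].labels


class TestFilterTemplate:
    def _chain(self, method="xray", resolution=2.0):
        return ChainStructure("A", [], "AAAA", method=method, resolution=resolution)

    def test_good_template_kept(self):
        keep, reason = filter_template(self._chain(), LabelTrack("1111"))
        assert keep and reason is None

    @pytest.mark.parametrize("kwargs,track,reason", [
        ({"resolution": 3.6}, "1111", "resolution"),
        ({"resolution": None}, "1111", "resolution"),
        ({"method": "nmr"}, "1111", "method"),
        ({}, "1100", "interface_count"),
        ({}, "11??", "interface_count"),
    ])
    def test_drop_reasons(self, kwargs, track, reason):
        keep, got = filter_template(self._chain(**kwargs), LabelTrack(track))
        assert not keep and got == reason

    def test_boundary_resolution_kept(self):
        keep, _ = filter_template(self._chain(resolution=3.5), LabelTrack("111"))
        assert keep


class TestPDBIO:
    def test_write_read_round_trip(self, tmp_path):
        chains, _, _ = make_complex(seed=2, missing_rate=0.2)
        path = tmp_path / "complex.pdb"
        with open(path, "w") as fh:
            write_pdb(chains, fh)
        loaded = read_pdb_chains(path)
        assert [c.chain_id for c in loaded] == [c.chain_id for c in chains]
        for orig, back in zip(chains, loaded):
            assert back.full_sequence == orig.full_sequence
            assert ([r.seq_index for r in back.resolved_residues()]
                    == [r.seq_index for r in orig.resolved_residues()])
            a0 = orig.resolved_residues()[0].atoms[0]
            b0 = back.resolved_residues()[0].atoms[0]
            assert (b0.x, b0.y, b0.z) == pytest.approx((a0.x, a0.y, a0.z), abs=1e-3)

    def test_labels_survive_pdb_round_trip(self, tmp_path):
        chains, union_tracks, _ = make_complex(seed=3)
        path = tmp_path / "complex.pdb"
        with open(path, "w") as fh:
            write_pdb(chains, fh)
        tracks = label_interfaces(read_pdb_chains(path))
        for cid, track in tracks.items():
            assert track.labels == union_tracks[cid].labels
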