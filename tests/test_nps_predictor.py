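"""Non-partner-specific prediction: filtering, zone cascade, majority vote."""

import numpy as np
import pytest

from homppi.blast_io import compute_stats
from homppi.nps_predictor import (
    NPSInterfacePredictor,
    Query,
    TemplateChain,
    filter_homologs,
    predict_nps,
    vote_transfer,
)
from homppi.simulate import make_complex, mutate_homolog
from homppi.structure_interface import LabelTrack
from homppi.zoning import Zone, classify_nps
from tests.conftest import make_record


def tmpl(template_id, sequence, labels, species="sp1", resolution=2.0,
         method="xray"):
    return TemplateChain(template_id, sequence, LabelTrack(labels),
                         species=species, method=method, resolution=resolution)


class TestFilterHomologs:
    QUERY = Query("q", "ACDEFGHIKL", species="sp_q")

    def _hit(self, template, identity=5):
        rec = make_record(self.QUERY.sequence, template.sequence,
                          n_identical=identity, n_positive=identity)
        return (template, rec)

    def test_self_hit_removed(self):
        template = tmpl("t_self", self.QUERY.sequence, "1110000000")
        kept, removed = filter_homologs(self.QUERY, [self._hit(template)])
        assert kept == [] and removed == [("t_self", "self")]

    def test_high_identity_same_species_removed(self):
        template = tmpl("t1", "ACDEFGHIKV", "1110000000", species="sp_q")
        kept, removed = filter_homologs(self.QUERY, [self._hit(template, identity=10)])
        assert removed == [("t1", "identity_species")]

    def test_high_identity_different_species_kept(self):
        template = tmpl("t1", "ACDEFGHIKV", "1110000000", species="sp_other")
        kept, removed = filter_homologs(self.QUERY, [self._hit(template, identity=10)])
        assert len(kept) == 1 and removed == []

    @pytest.mark.parametrize("kwargs,labels,reason", [
        ({"method": "nmr"}, "1110000000", "method"),
        ({"resolution": 3.7}, "1110000000", "resolution"),
        ({}, "1100000000", "interface_count"),
    ])
    def test_structure_quality_rules(self, kwargs, labels, reason):
        template = tmpl("t1", "ACDEFGHIKV", labels, **kwargs)
        kept, removed = filter_homologs(self.QUERY, [self._hit(template)])
        assert removed == [("t1", reason)]


class TestVoting:
    def test_majority_of_three(self):
        # one position where labels are (1, 1, 0) -> score 2/3, call 1
        seq = "AAAA"
        templates = [tmpl("t1", seq, "0100"), tmpl("t2", seq, "0100"),
                     tmpl("t3", seq, "0000")]
        ranked = [(t, make_record(seq, seq, template_id=t.template_id))
                  for t in templates]
        scores, calls, n_votes = vote_transfer(4, ranked)
        assert scores[1] == pytest.approx(2 / 3)
        assert calls == [0, 1, 0, 0]
        assert n_votes == [3, 3, 3, 3]

    def test_exact_tie_calls_interface(self):
        seq = "AA"
        ranked = [(tmpl("t1", seq, "10"), make_record(seq, seq, template_id="t1")),
                  (tmpl("t2", seq, "00"), make_record(seq, seq, template_id="t2"))]
        scores, calls, _ = vote_transfer(2, ranked)
        assert scores[0] == 0.5 and calls[0] == 1

    def test_missing_coordinates_abstain(self):
        seq = "AAA"
        ranked = [(tmpl("t1", seq, "?1?"), make_record(seq, seq, template_id="t1"))]
        scores, calls, n_votes = vote_transfer(3, ranked)
        assert scores == [None, 1.0, None]
        assert calls == [0, 1, 0]
        assert n_votes == [0, 1, 0]

    def test_gap_columns_abstain(self):
        # template deletion: query position 2 has no aligned residue
        ranked = [(tmpl("t1", "AA", "11"),
                   make_record("AAA", "A-A", template_id="t1"))]
        scores, calls, n_votes = vote_transfer(3, ranked)
        assert scores == [1.0, None, 1.0]
        assert n_votes == [1, 0, 1]

    @pytest.mark.parametrize("case_seed", range(25))
    def test_vote_oracle_exhaustive_recount(self, case_seed):
        """Scores match an exhaustive per-position recount on random cases."""
        rng = np.random.default_rng(1000 + case_seed)
        length = int(rng.integers(10, 31))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        ranked = []
        for t_i in range(int(rng.integers(1, 6))):
            labels = LabelTrack("".join(
                rng.choice(["0", "1", "?"], p=[0.5, 0.3, 0.2], size=length)))
            hom = mutate_homolog(seq, labels, sub_rate=0.2, indel_rate=0.15,
                                 seed=int(rng.integers(2**31)),
                                 template_id=f"t{t_i}")
            ranked.append((TemplateChain(f"t{t_i}", hom.sequence, hom.labels,
                                         resolution=2.0), hom.record))
        scores, calls, n_votes = vote_transfer(length, ranked)
        # oracle: explicit per-template coordinate maps, then recount
        pos = [0] * length
        neg = [0] * length
        for template, rec in ranked:
            q_map = np.cumsum([c != "-" for c in rec.q_aln]) + rec.q_start - 1
            t_map = np.cumsum([c != "-" for c in rec.t_aln]) + rec.t_start - 1
            for col in range(rec.lal):
                if rec.q_aln[col] == "-" or rec.t_aln[col] == "-":
                    continue
                label = template.labels[t_map[col] - 1]
                if label == "1":
                    pos[q_map[col] - 1] += 1
                elif label == "0":
                    neg[q_map[col] - 1] += 1
        for i in range(length):
            assert n_votes[i] == pos[i] + neg[i]
            if pos[i] + neg[i] == 0:
                assert scores[i] is None and calls[i] == 0
            else:
                assert scores[i] == pytest.approx(pos[i] / (pos[i] + neg[i]))
                assert calls[i] == (1 if scores[i] >= 0.5 else 0)


class TestPredictNPS:
    def _hits_from_homologs(self, seq, labels, n, sub_rate, seed):
        hits = []
        for i in range(n):
            hom = mutate_homolog(seq, labels, sub_rate=sub_rate,
                                 seed=seed + i, template_id=f"t{i}")
            hits.append((TemplateChain(f"t{i}", hom.sequence, hom.labels,
                                       species=f"sp{i}", resolution=2.0),
                         hom.record))
        return hits

    def test_single_template_identity_transfer(self):
        chains, union_tracks, _ = make_complex(seed=21, len_range=(150, 180))
        seq = chains[0].full_sequence
        labels = union_tracks["A"]
        hits = self._hits_from_homologs(seq, labels, 1, sub_rate=0.0, seed=50)
        pred = predict_nps(Query("q", seq), hits)
        assert pred.predicted
        assert pred.as_track().labels == labels.labels

    def test_zone_cascade_prefers_strictest_zone(self):
        chains, union_tracks, _ = make_complex(seed=22, len_range=(200, 240))
        seq = chains[0].full_sequence
        close = self._hits_from_homologs(seq, union_tracks["A"], 2,
                                         sub_rate=0.02, seed=60)
        far = self._hits_from_homologs(seq, union_tracks["A"], 2,
                                       sub_rate=0.65, seed=70)
        zones = {classify_nps(compute_stats(r)) for _, r in close}
        assert zones == {Zone.SAFE}
        pred = predict_nps(Query("q", seq), close + far)
        assert pred.zone_used == Zone.SAFE
        assert set(pred.templates_used) == {t.template_id for t, _ in close}

    def test_no_hits_is_not_predicted(self):
        pred = predict_nps(Query("q", "ACDEF"), [])
        assert not pred.predicted and pred.zone_used is None
        assert pred.calls == [0] * 5 and pred.scores == [None] * 5

    def test_at_most_k_templates(self):
        chains, union_tracks, _ = make_complex(seed=23, len_range=(200, 240))
        seq = chains[0].full_sequence
        hits = self._hits_from_homologs(seq, union_tracks["A"], 14,
                                        sub_rate=0.05, seed=80)
        pred = predict_nps(Query("q", seq), hits, k=10)
        assert len(pred.templates_used) == 10

    def test_deterministic(self):
        chains, union_tracks, _ = make_complex(seed=24, len_range=(150, 180))
        seq = chains[0].full_sequence
        hits = self._hits_from_homologs(seq, union_tracks["A"], 5,
                                        sub_rate=0.1, seed=90)
        p1 = predict_nps(Query("q", seq), hits)
        p2 = predict_nps(Query("q", seq), list(reversed(hits)))
        assert p1 == p2

    def test_estimator_wrapper_matches_function(self):
        chains, union_tracks, _ = make_complex(seed=25, len_range=(150, 180))
        seq = chains[0].full_sequence
        hits = self._hits_from_homologs(seq, union_tracks["A"], 3,
                                        sub_rate=0.1, seed=95)
        query = Query("q", seq, species="sp_q",
                      records=tuple(r for _, r in hits))
        predictor = NPSInterfacePredictor().fit([t for t, _ in hits])
        assert predictor.predict([query])[0] == predict_nps(query, hits)
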