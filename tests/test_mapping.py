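"""Terminal-motif extraction, matrix scoring, decoys and the PPV filter."""

import numpy as np
import pytest
from _oracles import map_exhaustive

from peptimark import (CleavageMotif, PeptideRecord, SpecificityMatrix,
                       ValidationError, compute_ppv, extract_terminal_motifs,
                       generate_decoys, map_proteases, read_matrices_json,
                       score_motif, write_matrices_json)
from peptimark.mapping import RESIDUES, UNIFORM_BACKGROUND

PARENT = "MKWVTFISLLLLFSSAYS"


def uniform_matrix(pid="U", threshold=0.0):
    return SpecificityMatrix(pid, np.full((8, 20), 1 / 20), threshold)


def one_hot_matrix(motif, pid="OH", threshold=0.0):
    w = np.zeros((8, 20))
    for j, ch in enumerate(motif):
        w[j, RESIDUES.index(ch)] = 1.0
    return SpecificityMatrix(pid, w, threshold)


class TestMotifExtraction:
    def test_internal_peptide_by_hand(self):
        rec = PeptideRecord(600.0, 25.0, 1.0, sequence=PARENT[4:10],
                            parent_id="P", start=5, end=10)
        n_motif, c_motif = extract_terminal_motifs(rec, PARENT, "m1")
        assert n_motif.residues == "MKWVTFIS"
        assert c_motif.residues == "ISLLLLFS"
        assert n_motif.position == 4 and c_motif.position == 10

    def test_protein_start_padded_with_x(self):
        rec = PeptideRecord(500.0, 25.0, 1.0, sequence=PARENT[0:5],
                            parent_id="P", start=1, end=5)
        n_motif, _ = extract_terminal_motifs(rec, PARENT, "m1")
        assert n_motif.residues == "XXXX" + PARENT[:4]

    def test_coordinates_beyond_parent_rejected(self):
        rec = PeptideRecord(500.0, 25.0, 1.0, parent_id="P", start=15, end=25)
        with pytest.raises(ValidationError):
            extract_terminal_motifs(rec, PARENT, "m1")


class TestScoring:
    def test_uniform_matrix_scores_zero(self):
        assert score_motif(uniform_matrix(), "ACDEFGHI") == pytest.approx(0.0)

    def test_one_hot_exact_match_is_8_log2_20(self):
        m = one_hot_matrix("ACDEFGHI")
        assert score_motif(m, "ACDEFGHI") == pytest.approx(8 * np.log2(20), abs=1e-9)

    def test_all_x_motif_scores_zero(self):
        m = one_hot_matrix("ACDEFGHI")
        assert score_motif(m, "XXXXXXXX") == 0.0

    def test_matrix_rows_must_be_distributions(self):
        with pytest.raises(ValidationError):
            SpecificityMatrix("bad", np.full((8, 20), 0.1), 0.0)


class TestDecoys:
    def test_count_and_reproducibility(self):
        a = generate_decoys(1000, seed=5)
        b = generate_decoys(1000, seed=5)
        assert len(a) == 1000 and a == b
        assert generate_decoys(1000, seed=6) != a
        assert all(len(d) == 8 and set(d) <= set(RESIDUES) for d in a[:50])

    def test_residue_frequencies_near_background(self):
        decoys = generate_decoys(12_500, seed=0)  # 1e5 residues
        pooled = "".join(decoys)
        n, p = len(pooled), 1 / 20
        bound = 3 * np.sqrt(n * p * (1 - p))
        for r in RESIDUES:
            assert abs(pooled.count(r) - n * p) < bound + 1


class TestMapping:
    def test_empty_matrix_list_yields_no_assignments(self):
        motifs = [CleavageMotif("m1", "N", "ACDEFGHI")]
        assert map_proteases(motifs, []) == []

    def test_one_hot_matrix_hits_its_own_motif_once(self):
        m = one_hot_matrix("ACDEFGHI", threshold=10.0)
        motifs = [CleavageMotif("m1", "N", "ACDEFGHI"),
                  CleavageMotif("m2", "C", "WWWWWWWW")]
        hits = map_proteases(motifs, [m])
        assert len(hits) == 1
        assert (hits[0].marker_id, hits[0].terminus) == ("m1", "N")

    def test_matches_exhaustive_oracle(self, rng):
        # small random instances against scalar-by-scalar enumeration
        for trial in range(5):
            matrices = []
            for k in range(3):
                w = rng.dirichlet(np.ones(20), size=8)
                matrices.append(SpecificityMatrix(f"P{k}", w,
                                                  float(rng.normal(0, 5))))
            motifs = [
                CleavageMotif(f"m{i}", "N",
                              "".join(rng.choice(list(RESIDUES), 8)))
                for i in range(5)
            ]
            got = {(a.protease_id, a.marker_id, a.terminus)
                   for a in map_proteases(motifs, matrices)}
            assert got == map_exhaustive(motifs, matrices)

    def test_raising_threshold_never_adds_assignments(self, rng):
        w = rng.dirichlet(np.ones(20), size=8)
        motifs = [CleavageMotif(f"m{i}", "N",
                                "".join(rng.choice(list(RESIDUES), 8)))
                  for i in range(40)]
        counts = []
        for thr in (-20.0, -10.0, 0.0, 10.0):
            m = SpecificityMatrix("P", w, thr)
            counts.append(len(map_proteases(motifs, [m])))
        assert counts == sorted(counts, reverse=True)


class TestPPV:
    def _hit(self, pid, marker, site):
        from peptimark.mapping import ProteaseAssignment
        return ProteaseAssignment(pid, marker, "N", 5.0, "P", site)

    def test_ppv_exactly_at_cutoff_not_retained(self):
        targets = [self._hit("A", f"m{i}", i) for i in range(13)]
        decoys = [self._hit("A", f"d{i}", None) for i in range(7)]
        (rep,) = compute_ppv(targets, decoys, n_targets=100, n_decoys=100)
        assert rep.ppv == pytest.approx(0.65)
        assert not rep.retained  # strictly greater than 0.65 required

    def test_ppv_above_cutoff_with_enough_sites_retained(self):
        targets = [self._hit("A", f"m{i}", i) for i in range(14)]
        decoys = [self._hit("A", f"d{i}", None) for i in range(6)]
        (rep,) = compute_ppv(targets, decoys, n_targets=100, n_decoys=100)
        assert rep.ppv == pytest.approx(0.70)
        assert rep.n_sites == 14
        assert rep.retained

    def test_site_rule_blocks_perfect_ppv(self):
        targets = [self._hit("A", f"m{i}", i % 3) for i in range(20)]
        (rep,) = compute_ppv(targets, [], n_targets=100, n_decoys=100)
        assert rep.ppv == 1.0
        assert rep.n_sites == 3
        assert not rep.retained

    def test_decoy_scaling_is_linear(self):
        targets = [self._hit("A", f"m{i}", i) for i in range(10)]
        decoys = [self._hit("A", f"d{i}", None) for i in range(40)]
        (rep,) = compute_ppv(targets, decoys, n_targets=100, n_decoys=400)
        assert rep.decoy_hits_scaled == pytest.approx(10.0)
        assert rep.ppv == pytest.approx(0.5)

    def test_raising_ppv_cutoff_shrinks_retained_set(self):
        targets = ([self._hit("A", f"m{i}", i) for i in range(14)]
                   + [self._hit("B", f"q{i}", i) for i in range(8)])
        decoys = ([self._hit("A", f"d{i}", None) for i in range(6)]
                  + [self._hit("B", f"e{i}", None) for i in range(4)])
        retained = []
        for cutoff in (0.5, 0.65, 0.8, 0.95):
            reps = compute_ppv(targets, decoys, 100, 100, ppv_cutoff=cutoff)
            retained.append({r.protease_id for r in reps if r.retained})
        for small, large in zip(retained[1:], retained[:-1]):
            assert small <= large


def test_matrices_json_round_trip(tmp_path):
    m = one_hot_matrix("ACDEFGHI", threshold=3.5)
    path = tmp_path / "matrices.json"
    write_matrices_json([m], path)
    (back,) = read_matrices_json(path)
    assert back.protease_id == m.protease_id
    assert back.score_threshold == 3.5
    assert np.array_equal(back.weights, m.weights)
    assert np.array_equal(back.background, UNIFORM_BACKGROUND)
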