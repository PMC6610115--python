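import numpy as np
import pytest

import networkx as nx
from alignment_oracle import brute_global_score, brute_local_score
from genorigin.homology import (
    ScoringScheme,
    best_hits,
    build_orthogroups,
    encode,
    estimate_evalue,
    global_align,
    homolog_fraction,
    in_paralog_pairs,
    local_align,
    reciprocal_best_hits,
    score_matrix,
)
from genorigin.seqio import Proteome, ProteinRecord
from genorigin.simulate import SimulationConfig, evolve_sequence, sample_root_sequence, simulate_dataset
from genorigin import _swkernel


def random_proteome(species, n, length, seed):
    return Proteome(
        species,
        [
            ProteinRecord(f"{species}{i:03d}", species, sample_root_sequence(length, seed + i))
            for i in range(n)
        ],
    )


class TestAlignmentOracle:
    """Dynamic programming must agree with exhaustive path enumeration."""

    def test_scores_match_brute_force(self, match3_scoring):
        rng = np.random.default_rng(0)
        for _ in range(60):
            a = "".join(rng.choice(list("ACD"), rng.integers(0, 7)))
            b = "".join(rng.choice(list("ACD"), rng.integers(0, 7)))
            g = global_align(a, b, match3_scoring)
            assert g.score == brute_global_score(a, b, match3_scoring), (a, b)
            l = local_align(a, b, match3_scoring)
            assert l.score == brute_local_score(a, b, match3_scoring), (a, b)
            # removing gaps must recover the inputs
            assert g.aligned_a.replace("-", "") == a
            assert g.aligned_b.replace("-", "") == b

    def test_kernel_agrees_with_traceback_aligner(self, scoring):
        """The batched score kernel and PairwiseAligner are independent routes."""
        rng = np.random.default_rng(1)
        seqs = []
        for i in range(20):
            root = sample_root_sequence(int(rng.integers(30, 160)), 100 + i)
            seqs.append(root)
            seqs.append(evolve_sequence(root, 0.4, 200 + i))
        enc = [encode(s) for s in seqs]
        mat = _swkernel.batch_scores(
            enc, enc, scoring.padded_matrix, scoring.gap_open, scoring.gap_extend
        )
        for i in range(0, len(seqs), 5):
            for j in range(1, len(seqs), 7):
                assert mat[i, j] == local_align(seqs[i], seqs[j], scoring).score


class TestAlignmentProperties:
    def test_identical_sequences_score_diagonal_sum(self, scoring):
        res = global_align("ACDE", "ACDE", scoring)
        diag = sum(
            scoring.matrix[encode(c)[0], encode(c)[0]] for c in "ACDE"
        )
        assert res.score == diag
        assert res.identity_fraction == 1.0

    def test_empty_vs_sequence_forced_gap(self, scoring):
        res = global_align("", "ACDE", scoring)
        assert res.score == -(scoring.gap_open + 3 * scoring.gap_extend)
        assert res.aligned_a == "----"

    def test_score_symmetric(self, scoring):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = sample_root_sequence(int(rng.integers(0, 40)), rng.integers(1e6))
            b = sample_root_sequence(int(rng.integers(0, 40)), rng.integers(1e6))
            assert global_align(a, b, scoring).score == global_align(b, a, scoring).score
            assert local_align(a, b, scoring).score == local_align(b, a, scoring).score

    def test_local_no_positive_pair_gives_empty(self, match3_scoring):
        res = local_align("AAAA", "CCCC", match3_scoring)
        assert res.score == 0
        assert res.aligned_a == ""

    def test_local_substring_at_least_global_self(self, scoring):
        inner = global_align("ACDE", "ACDE", scoring).score
        assert local_align("ACDE", "GGACDEGG", scoring).score >= inner

    def test_illegal_characters_rejected(self, scoring):
        with pytest.raises(ValueError):
            global_align("ACJ", "ACD", scoring)


class TestEvalue:
    def test_monotone_decreasing_in_score(self, scoring):
        evs = [estimate_evalue(s, 100, 100, scoring) for s in range(0, 100, 5)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_linear_in_subject_length(self, scoring):
        assert estimate_evalue(40, 100, 2000, scoring) == pytest.approx(
            2 * estimate_evalue(40, 100, 1000, scoring)
        )

    def test_reference_value(self, scoring):
        assert estimate_evalue(40, 100, 100, scoring) == pytest.approx(9.4e-3, rel=5e-3)

    def test_nonpositive_lengths_rejected(self, scoring):
        with pytest.raises(ValueError):
            estimate_evalue(40, 0, 100, scoring)


@pytest.fixture(scope="module")
def twin_proteomes():
    p = random_proteome("p", 12, 120, 500)
    q = Proteome("q", [ProteinRecord(r.id.replace("p", "q"), "q", r.sequence) for r in p])
    return p, q


class TestBestHits:
    def test_identical_proteomes_hit_their_copies(self, scoring, twin_proteomes):
        p, q = twin_proteomes
        hits = best_hits(p, q, scoring)
        assert len(hits) == len(p)
        for pid, hit in hits.items():
            assert hit.subject_id == pid.replace("p", "q")

    def test_unrelated_proteomes_no_hits(self, scoring):
        p = random_proteome("p", 8, 100, 900)
        q = random_proteome("q", 8, 100, 5900)
        assert best_hits(p, q, scoring) == {}

    def test_rbh_symmetry(self, scoring):
        ds = simulate_dataset(SimulationConfig(n_families=25, n_unique=4, n_multicopy=0, sequence_length=120))
        n, a = ds.proteomes["N"], ds.proteomes["A"]
        fwd = reciprocal_best_hits(n, a, scoring)
        rev = reciprocal_best_hits(a, n, scoring)
        assert {(y, x) for x, y in fwd} == rev
        assert len(fwd) == 25

    def test_self_rbh_gives_self_pairs(self, scoring, twin_proteomes):
        p, q = twin_proteomes
        pairs = reciprocal_best_hits(p, q, scoring)
        assert pairs == {(r.id, r.id.replace("p", "q")) for r in p}

    def test_in_paralogs_find_planted_duplicates(self, scoring):
        recs = []
        for i in range(6):
            root = sample_root_sequence(150, 700 + i)
            recs.append(ProteinRecord(f"g{i}a", "s", root))
            recs.append(ProteinRecord(f"g{i}b", "s", evolve_sequence(root, 0.3, 800 + i)))
        p = Proteome("s", recs)
        pairs = in_paralog_pairs(p, scoring)
        assert pairs == {(f"g{i}a", f"g{i}b") for i in range(6)}

    def test_best_hits_prefer_ortholog_over_distant_paralog(self, scoring):
        """With a decoy paralog planted far away (distance 1.5), queries
        still pick the true ortholog."""
        p_recs, q_recs = [], []
        for i in range(12):
            root = sample_root_sequence(200, 2000 + i)
            p_recs.append(ProteinRecord(f"p{i:02d}", "p", root))
            q_recs.append(
                ProteinRecord(f"q{i:02d}", "q", evolve_sequence(root, 0.6, 2100 + i))
            )
            q_recs.append(
                ProteinRecord(f"q{i:02d}x", "q", evolve_sequence(root, 1.5, 2200 + i))
            )
        hits = best_hits(Proteome("p", p_recs), Proteome("q", q_recs), scoring)
        assert len(hits) == 12
        assert all(hit.subject_id == pid.replace("p", "q") for pid, hit in hits.items())

    def test_in_paralogs_anchor_on_ortholog_scores(self, scoring):
        """A within-species pair only counts as a duplication when both
        members have an ortholog and the pair outscores the weaker one
        (InParanoid anchoring)."""
        root = sample_root_sequence(150, 750)
        p = Proteome(
            "s",
            [
                ProteinRecord("ga", "s", root),
                ProteinRecord("gb", "s", evolve_sequence(root, 0.3, 751)),
            ],
        )
        pair_score = best_hits(p, p, scoring)["ga"].score
        ok = {"ga": pair_score * 2, "gb": pair_score / 2}
        assert in_paralog_pairs(p, scoring, cross_best=ok) == {("ga", "gb")}
        # stronger than both ortholog anchors -> not a post-speciation pair
        toostrong = {"ga": pair_score * 2, "gb": pair_score * 1.5}
        assert in_paralog_pairs(p, scoring, cross_best=toostrong) == set()
        # a member with no ortholog at all cannot anchor an in-paralog pair
        assert in_paralog_pairs(p, scoring, cross_best={"ga": 1.0}) == set()


class TestOrthogroups:
    def test_single_triplet(self):
        groups = build_orthogroups({("n1", "a1")}, {("n1", "p1")}, {("a1", "p1")})
        assert len(groups) == 1
        assert groups[0].single_copy
        assert groups[0].members == {"N": ["n1"], "A": ["a1"], "P": ["p1"]}

    def test_within_species_edge_makes_multicopy(self):
        groups = build_orthogroups(
            {("n1", "a1")}, {("n1", "p1")}, {("a1", "p1")},
            within={"N": {("n1", "n2")}},
        )
        assert len(groups) == 1
        assert not groups[0].single_copy
        assert groups[0].members["N"] == ["n1", "n2"]

    def test_membership_is_a_partition(self, scoring):
        ds = simulate_dataset(SimulationConfig(n_families=30, n_unique=5, n_multicopy=5, sequence_length=120))
        n, a, p = (ds.proteomes[s] for s in "NAP")
        groups = build_orthogroups(
            reciprocal_best_hits(n, a, scoring),
            reciprocal_best_hits(n, p, scoring),
            reciprocal_best_hits(a, p, scoring),
            within={"N": in_paralog_pairs(n, scoring)},
        )
        seen = [
            (s, m) for g in groups for s, ms in g.members.items() for m in ms
        ]
        assert len(seen) == len(set(seen))

    def test_components_match_graph_oracle(self):
        """Union-find components equal networkx components on random graphs."""
        rng = np.random.default_rng(3)
        for trial in range(20):
            n_vert = int(rng.integers(2, 12))
            na = {(f"n{i}", f"a{rng.integers(n_vert)}") for i in rng.integers(0, n_vert, 6)
                  for i in [i]}
            np_ = {(f"n{i}", f"p{rng.integers(n_vert)}") for i in rng.integers(0, n_vert, 6)
                   for i in [i]}
            ap = {(f"a{i}", f"p{rng.integers(n_vert)}") for i in rng.integers(0, n_vert, 6)
                  for i in [i]}
            groups = build_orthogroups(na, np_, ap)
            g = nx.Graph()
            g.add_edges_from((("N", x), ("A", y)) for x, y in na)
            g.add_edges_from((("N", x), ("P", y)) for x, y in np_)
            g.add_edges_from((("A", x), ("P", y)) for x, y in ap)
            ours = sorted(
                tuple(sorted((s, m) for s, ms in og.members.items() for m in ms))
                for og in groups
            )
            theirs = sorted(tuple(sorted(c)) for c in nx.connected_components(g))
            assert ours == theirs
            # forest identity when acyclic
            if nx.is_forest(g):
                assert len(groups) == g.number_of_nodes() - g.number_of_edges()


class TestHomologFraction:
    def test_self_reference_is_100(self, scoring, twin_proteomes):
        p, q = twin_proteomes
        assert homolog_fraction(p, q, scoring) == 100.0

    def test_unrelated_is_0(self, scoring):
        p = random_proteome("p", 6, 100, 111)
        q = random_proteome("q", 6, 100, 999)
        assert homolog_fraction(p, q, scoring) == 0.0

    def test_empty_query_rejected(self, scoring):
        with pytest.raises(ValueError):
            homolog_fraction(Proteome("p"), random_proteome("q", 3, 50, 5), scoring)

    def test_partial_sharing_recovered(self, scoring):
        """~40% shared families -> fraction near 40 (binomial band)."""
        rng_base = 3000
        shared, total = 40, 100
        p_recs, q_recs = [], []
        for i in range(total):
            root = sample_root_sequence(150, rng_base + i)
            p_recs.append(ProteinRecord(f"p{i:03d}", "p", root))
            if i < shared:
                q_recs.append(
                    ProteinRecord(f"q{i:03d}", "q", evolve_sequence(root, 0.6, rng_base + 500 + i))
                )
            else:
                q_recs.append(
                    ProteinRecord(f"q{i:03d}", "q", sample_root_sequence(150, rng_base + 900 + i))
                )
        frac = homolog_fraction(Proteome("p", p_recs), Proteome("q", q_recs), scoring)
        se = 100 * (0.4 * 0.6 / total) ** 0.5
        assert abs(frac - 40.0) <= 3 * se


class TestScoringSchemeValidation:
    def test_asymmetric_matrix_rejected(self):
        mat = np.zeros((21, 21), dtype=int)
        mat[0, 1] = 5
        with pytest.raises(ValueError, match="symmetric"):
            ScoringScheme(matrix=mat)

    def test_gap_order_enforced(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=1, gap_extend=2)
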