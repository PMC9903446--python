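"""AMOVA unit tests, checked against a definitional pair-sum oracle.

The oracle computes every sum of squares by explicit enumeration of pairs
(SS over a set S of individuals = sum over unordered pairs within S of the
squared distance, divided by |S|) and recovers variance components by
solving the expected-mean-square equations with textbook weighted-size
coefficients, independently of the package's vectorised implementation.
"""

import itertools

import numpy as np
import pytest

from cmschimera.amova import DistanceMatrix, amova, distance_matrix
from cmschimera.io import SequenceRecord


def pairsum_oracle(d2, pops, groups):
    """Brute-force AMOVA from the definitional formulas (explicit loops)."""
    labels = list(pops)
    N = len(labels)

    def ss_of(ids):
        total = 0.0
        for a, b in itertools.combinations(ids, 2):
            total += d2[labels.index(a)][labels.index(b)]
        return total / len(ids)

    pop_ids = {}
    for l in labels:
        pop_ids.setdefault(pops[l], []).append(l)
    group_ids = {}
    for p, ids in pop_ids.items():
        group_ids.setdefault(groups[p], []).extend(ids)

    ss_total = ss_of(labels)
    ss_wp = sum(ss_of(ids) for ids in pop_ids.values())
    ss_wg = sum(ss_of(ids) for ids in group_ids.values())
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    P, G = len(pop_ids), len(group_ids)
    sizes = {p: len(ids) for p, ids in pop_ids.items()}
    gsizes = {g: len(ids) for g, ids in group_ids.items()}
    vc = ss_wp / (N - P)
    sq_over_g = sum(
        sum(sizes[p] ** 2 for p in pop_ids if groups[p] == g) / gsizes[g]
        for g in group_ids
    )
    n2 = (sq_over_g - sum(s**2 for s in sizes.values()) / N) / (G - 1)
    n3 = (N - sum(s**2 for s in gsizes.values()) / N) / (G - 1)
    if P == G:
        vb = 0.0
    else:
        n1 = (N - sq_over_g) / (P - G)
        vb = (ss_ap / (P - G) - vc) / n1
    va = (ss_ag / (G - 1) - vc - n2 * vb) / n3
    return {
        "ss": (ss_ag, ss_ap, ss_wp, ss_total),
        "components": (va, vb, vc),
    }


def _survey_inputs(survey):
    d = distance_matrix(survey.bundle.records, mode="haplotype_binary")
    pops = {r.id: r.population for r in survey.bundle.records}
    return d, pops, survey.bundle.group_map


class TestDistanceMatrix:
    def test_same_haplotype_distance_zero(self):
        recs = [SequenceRecord("a", "P", "ACGT"), SequenceRecord("b", "P", "ACGT")]
        assert distance_matrix(recs).values[0, 1] == 0.0

    def test_different_haplotype_distance_one(self):
        recs = [SequenceRecord("a", "P", "ACGT"), SequenceRecord("b", "P", "ACGA")]
        assert distance_matrix(recs, mode="haplotype_binary").values[0, 1] == 1.0

    def test_nt_differences_squared(self):
        recs = [SequenceRecord("a", "P", "ACGT"), SequenceRecord("b", "P", "AGGA")]
        assert distance_matrix(recs, mode="nt_differences").values[0, 1] == 4.0

    def test_nt_differences_ignore_missing(self):
        recs = [SequenceRecord("a", "P", "ACGN"), SequenceRecord("b", "P", "AGG?")]
        assert distance_matrix(recs, mode="nt_differences").values[0, 1] == 1.0

    def test_nt_differences_need_equal_lengths(self):
        recs = [SequenceRecord("a", "P", "ACGT"), SequenceRecord("b", "P", "ACG")]
        with pytest.raises(ValueError, match="aligned"):
            distance_matrix(recs, mode="nt_differences")

    def test_explicit_assignments_override_sequences(self):
        recs = [SequenceRecord("a", "P", "ACGT"), SequenceRecord("b", "P", "ACGT")]
        d = distance_matrix(recs, assignments={"a": "H1", "b": "H2"})
        assert d.values[0, 1] == 1.0


class TestAmovaSurveyDesign:
    def test_reproduces_published_table(self, survey):
        d, pops, groups = _survey_inputs(survey)
        res = amova(d, pops, groups)
        assert res.ss["among_groups"] == pytest.approx(3.462, abs=5e-4)
        assert res.ss["among_pops_within_groups"] == pytest.approx(15.0)
        assert res.ss["within_pops"] == 0.0
        assert res.ss["total"] == pytest.approx(18.462, abs=5e-4)
        assert res.df == {
            "among_groups": 1,
            "among_pops_within_groups": 3,
            "within_pops": 60,
            "total": 64,
        }
        assert res.variance_components["Va"] == pytest.approx(0.16667, abs=5e-6)
        assert res.variance_components["Vb"] == pytest.approx(0.33333, abs=5e-6)
        assert res.variance_components["Vc"] == 0.0
        assert res.percentages["Va"] == pytest.approx(33.33, abs=5e-3)
        assert res.percentages["Vb"] == pytest.approx(66.67, abs=5e-3)
        assert res.phi["phi_ct"] == pytest.approx(0.33333, abs=5e-6)
        assert res.phi["phi_sc"] == pytest.approx(1.0)
        assert res.phi["phi_st"] == pytest.approx(1.0)

    def test_matches_pairsum_oracle(self, survey):
        d, pops, groups = _survey_inputs(survey)
        res = amova(d, pops, groups)
        oracle = pairsum_oracle(d.values.tolist(), pops, groups)
        got_ss = (
            res.ss["among_groups"],
            res.ss["among_pops_within_groups"],
            res.ss["within_pops"],
            res.ss["total"],
        )
        assert got_ss == pytest.approx(oracle["ss"], abs=1e-9)
        got_comp = tuple(res.variance_components[k] for k in ("Va", "Vb", "Vc"))
        assert got_comp == pytest.approx(oracle["components"], abs=1e-9)


class TestAmovaGeneral:
    def test_two_pop_explicit_distances_match_oracle(self):
        labels = ["a1", "a2", "b1", "b2"]
        d2 = np.array(
            [
                [0, 1, 4, 9],
                [1, 0, 1, 4],
                [4, 1, 0, 1],
                [9, 4, 1, 0],
            ],
            dtype=float,
        )
        pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        groups = {"A": "G1", "B": "G2"}
        res = amova(DistanceMatrix(labels, d2), pops, groups)
        oracle = pairsum_oracle(d2.tolist(), pops, groups)
        assert (
            res.ss["among_groups"],
            res.ss["among_pops_within_groups"],
            res.ss["within_pops"],
            res.ss["total"],
        ) == pytest.approx(oracle["ss"], abs=1e-12)
        assert tuple(
            res.variance_components[k] for k in ("Va", "Vb", "Vc")
        ) == pytest.approx(oracle["components"], abs=1e-12)

    def test_random_designs_match_oracle_and_ss_additivity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n_pops = rng.integers(3, 6)
            sizes = rng.integers(2, 5, size=n_pops)
            labels, pops = [], {}
            for p in range(n_pops):
                for i in range(sizes[p]):
                    lab = f"p{p}_{i}"
                    labels.append(lab)
                    pops[lab] = f"P{p}"
            groups = {f"P{p}": ("G1" if p < n_pops // 2 + 1 else "G2") for p in range(n_pops)}
            n = len(labels)
            half = rng.integers(0, 5, size=(n, n)).astype(float)
            d2 = np.triu(half, 1)
            d2 = d2 + d2.T
            res = amova(DistanceMatrix(labels, d2), pops, groups)
            oracle = pairsum_oracle(d2.tolist(), pops, groups)
            assert (
                res.ss["among_groups"],
                res.ss["among_pops_within_groups"],
                res.ss["within_pops"],
                res.ss["total"],
            ) == pytest.approx(oracle["ss"], abs=1e-9)
            assert tuple(
                res.variance_components[k] for k in ("Va", "Vb", "Vc")
            ) == pytest.approx(oracle["components"], abs=1e-9)
            assert (
                res.ss["among_groups"]
                + res.ss["among_pops_within_groups"]
                + res.ss["within_pops"]
            ) == pytest.approx(res.ss["total"], abs=1e-9)

    def test_all_identical_records_degenerate(self):
        labels = [f"r{i}" for i in range(6)]
        d2 = np.zeros((6, 6))
        pops = {l: ("A" if i < 3 else "B") for i, l in enumerate(labels)}
        res = amova(DistanceMatrix(labels, d2), pops, {"A": "G1", "B": "G2"}, n_perm=10, seed=0)
        assert res.ss["total"] == 0.0
        assert res.phi["phi_st"] is None
        assert res.p_values == {}

    def test_single_group_gives_single_level_analysis(self, survey):
        d, pops, _ = _survey_inputs(survey)
        res = amova(d, pops, group_map=None)
        assert res.phi["phi_ct"] is None
        assert res.phi["phi_st"] == res.phi["phi_sc"]
        assert res.df["among_pops_within_groups"] == 4
        assert "among_groups" not in res.ss

    def test_phi_st_one_iff_monomorphic_populations(self, survey):
        d, pops, groups = _survey_inputs(survey)
        res = amova(d, pops, groups)
        assert res.ss["within_pops"] == 0.0
        assert res.phi["phi_st"] == pytest.approx(1.0)

    def test_permutation_pvalues_reproducible_and_order_invariant(self, survey):
        d, pops, groups = _survey_inputs(survey)
        res1 = amova(d, pops, groups, n_perm=200, seed=7)
        res2 = amova(d, pops, groups, n_perm=200, seed=7)
        assert res1.p_values == res2.p_values
        # shuffle record order: same seed must give the same p-values
        order = np.random.default_rng(0).permutation(d.n)
        d_shuf = DistanceMatrix(
            [d.labels[i] for i in order], d.values[np.ix_(order, order)]
        )
        res3 = amova(d_shuf, pops, groups, n_perm=200, seed=7)
        assert res3.p_values == res1.p_values

    def test_missing_population_mapping_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="population"):
            amova(d, {"a": "A"}, {"A": "G1"})

    def test_table_output_columns(self, survey):
        d, pops, groups = _survey_inputs(survey)
        frame = amova(d, pops, groups).to_frame()
        assert list(frame["Source of variation"]) == [
            "Among groups",
            "Among populations within groups",
            "Within populations",
            "Total",
        ]
        assert frame["d.f."].iloc[-1] == 64
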