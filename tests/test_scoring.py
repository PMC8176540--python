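"""Sample-set partitioning, gene masks, RPOS score, and RDC."""

import numpy as np
import pytest

import _naive
from conftest import make_data, random_labels
from rpos.core import GeneIntervalProfile, Interval, SelectionConfig
from rpos.intervals import gene_profile
from rpos.scoring import (
    gene_mask_row,
    non_outlier_set,
    partition_overlap,
    relative_dominant_class,
    rpos_score,
    score_all_genes,
    score_gene,
)


def profile(r0, r1):
    from rpos.intervals import overlap_interval, total_core_interval

    return GeneIntervalProfile(
        class0_interval=r0,
        class1_interval=r1,
        overlap=overlap_interval(r0, r1),
        total=total_core_interval(r0, r1),
    )


class TestNonOutlierSet:
    def test_membership_in_own_class_interval(self):
        prof = profile(Interval(0, 1), Interval(2, 3))
        row = np.array([0.5, 0.0, 2.5, 1.5])  # last class-1 value is outside R1
        labels = np.array([0, 0, 1, 1])
        assert non_outlier_set(row, labels, prof) == {0, 1, 2}

    def test_closed_endpoints_keep_boundary_samples(self):
        prof = profile(Interval(0, 1), Interval(2, 3))
        row = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 1, 1])
        assert non_outlier_set(row, labels, prof) == {0, 1, 2, 3}

    def test_value_in_other_class_interval_only_is_outlier(self):
        prof = profile(Interval(0, 1), Interval(2, 3))
        row = np.array([0.5, 2.5, 2.5, 0.5])  # samples 1 and 3 sit in the wrong interval
        labels = np.array([0, 0, 1, 1])
        assert non_outlier_set(row, labels, prof) == {0, 2}


class TestPartitionOverlap:
    def test_toy_membership(self):
        prof = profile(Interval(0, 2), Interval(1, 4))  # overlap [1, 2]
        row = np.array([0.5, 1.5, 1.8, 3.0])
        nonov, ov = partition_overlap({0, 1, 2, 3}, row, prof)
        assert ov == {1, 2}
        assert nonov == {0, 3}

    def test_empty_overlap_puts_everything_in_nonoverlapped(self):
        prof = profile(Interval(0, 1), Interval(2, 3))
        row = np.array([0.5, 0.6, 2.5, 2.6])
        nonov, ov = partition_overlap({0, 1, 2, 3}, row, prof)
        assert ov == set() and nonov == {0, 1, 2, 3}

    def test_all_inside_overlap(self):
        prof = profile(Interval(0, 4), Interval(0, 4))
        row = np.array([1.0, 2.0, 3.0, 3.5])
        nonov, ov = partition_overlap({0, 1, 2, 3}, row, prof)
        assert ov == {0, 1, 2, 3} and nonov == set()


def test_gene_mask_marks_unambiguous_samples_only():
    prof = profile(Interval(0, 2), Interval(1, 4))
    row = np.array([0.5, 1.5, 1.8, 3.0])
    labels = np.array([0, 0, 1, 1])
    assert gene_mask_row(row, labels, prof).tolist() == [True, False, False, True]


class TestRposScore:
    def test_direct_arithmetic(self):
        prof = GeneIntervalProfile(
            Interval(0, 2), Interval(1, 3), overlap=Interval(0, 1), total=Interval(0, 2)
        )
        val = rpos_score(prof, nonoutlier=set(range(8)), overlapped={0, 1, 2, 3},
                         per_class_overlap_counts=(2, 2))
        assert val == pytest.approx(4 * 0.5 * 0.5 * 0.25)  # 0.25

    def test_unbalanced_class_counts(self):
        prof = GeneIntervalProfile(
            Interval(0, 2), Interval(1, 3), overlap=Interval(0, 1), total=Interval(0, 2)
        )
        val = rpos_score(prof, set(range(8)), {0, 1, 2, 3}, (3, 1))
        assert val == pytest.approx(4 * 0.5 * 0.5 * (3 / 4) * (1 / 4))  # 0.1875

    def test_no_overlapped_samples_scores_zero(self):
        prof = GeneIntervalProfile(
            Interval(0, 1), Interval(2, 3), Interval.empty_interval(), Interval(0, 3)
        )
        assert rpos_score(prof, {0, 1, 2}, set(), (0, 0)) == 0.0

    def test_maximal_ambiguity_scores_one(self):
        prof = GeneIntervalProfile(
            Interval(0, 2), Interval(0, 2), overlap=Interval(0, 2), total=Interval(0, 2)
        )
        assert rpos_score(prof, set(range(8)), set(range(8)), (4, 4)) == pytest.approx(1.0)

    def test_degenerate_constant_gene_scores_one(self):
        prof = GeneIntervalProfile(
            Interval(5, 5), Interval(5, 5), overlap=Interval(5, 5), total=Interval(5, 5)
        )
        assert rpos_score(prof, set(range(4)), set(range(4)), (2, 2)) == 1.0

    def test_empty_nonoutlier_set_scores_one(self):
        prof = GeneIntervalProfile(
            Interval(0, 2), Interval(1, 3), Interval(1, 2), Interval(0, 3)
        )
        assert rpos_score(prof, set(), set(), (0, 0)) == 1.0


class TestRelativeDominantClass:
    def test_larger_masked_fraction_wins(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        mask = np.array([1, 1, 0, 1, 0, 0, 0], dtype=bool)  # 2/3 vs 1/4
        assert relative_dominant_class(mask, labels) == 0

    def test_class1_wins_when_dominant(self):
        labels = np.array([0, 0, 1, 1])
        mask = np.array([0, 0, 1, 1], dtype=bool)
        assert relative_dominant_class(mask, labels) == 1

    @pytest.mark.parametrize(
        "mask", [[1, 0, 1, 0], [0, 0, 0, 0]], ids=["equal-fractions", "all-zero"]
    )
    def test_ties_go_to_class_zero(self, mask):
        labels = np.array([0, 0, 1, 1])
        assert relative_dominant_class(np.array(mask, dtype=bool), labels) == 0


class TestScoreAllGenes:
    def test_separated_gene_scores_zero_with_full_mask(self, cfg):
        data = make_data([[0.0, 1, 2, 10, 11, 12]], [0, 0, 0, 1, 1, 1])
        recs, masks = score_all_genes(data, cfg)
        assert recs[0].rpos == 0.0
        assert masks.bits[0].sum() == recs[0].n_nonoutlier

    def test_duplicated_gene_rows_get_identical_records(self, cfg, rng):
        row = rng.normal(size=12)
        data = make_data([row, row], random_labels(rng, 12))
        recs, masks = score_all_genes(data, cfg)
        assert recs[0].rpos == recs[1].rpos
        assert recs[0].n_overlapped == recs[1].n_overlapped
        assert np.array_equal(masks.bits[0], masks.bits[1])

    def test_gene_order_equivariance(self, cfg, rng):
        Z = rng.normal(size=(10, 16))
        labels = random_labels(rng, 16)
        data = make_data(Z, labels)
        perm = rng.permutation(10)
        data_p = make_data(Z[perm], labels, gene_ids=[f"g{j}" for j in perm])
        recs, _ = score_all_genes(data, cfg)
        recs_p, _ = score_all_genes(data_p, cfg)
        for k, j in enumerate(perm):
            assert recs_p[k].rpos == recs[j].rpos
            assert recs_p[k].gene_id == recs[j].gene_id

    def test_partition_identities_on_random_genes(self, cfg, rng):
        """O' and O partition N; mask row sums to |O'|; class counts sum to |O|."""
        for _ in range(200):
            n = int(rng.integers(6, 30))
            labels = random_labels(rng, n)
            row = rng.normal(size=n)
            prof = gene_profile(row, labels, cfg)
            N = non_outlier_set(row, labels, prof)
            Op, O = partition_overlap(N, row, prof)
            assert Op | O == N and Op & O == set()
            mask = gene_mask_row(row, labels, prof)
            assert mask.sum() == len(Op)
            rec, _ = score_gene(row, labels, cfg)
            assert sum(rec.n_overlapped_by_class) == rec.n_overlapped == len(O)
            assert rec.n_nonoutlier == len(N)

    @pytest.mark.parametrize("dispersion", ["mad", "iqr"])
    def test_pipeline_matches_naive_definitions(self, dispersion, rng):
        """Independent loop-based oracle vs the vectorised pipeline on
        random small genes: sets and counts exact, reals to 1e-12."""
        cfg = SelectionConfig(dispersion=dispersion)
        for _ in range(250):
            n = int(rng.integers(6, 30))
            labels = random_labels(rng, n)
            row = rng.normal(scale=rng.uniform(0.5, 5), size=n)
            expected = _naive.score_gene(row.tolist(), labels.tolist(),
                                         dispersion=dispersion)
            data = make_data(row[None, :], labels)
            recs, masks = score_all_genes(data, cfg)
            assert recs[0].n_nonoutlier == len(expected["N"])
            assert recs[0].n_overlapped == len(expected["O"])
            assert recs[0].n_overlapped_by_class == expected["counts"]
            assert masks.bits[0].astype(int).tolist() == expected["mask"]
            assert recs[0].rdc == expected["rdc"]
            assert recs[0].rpos == pytest.approx(expected["rpos"], rel=1e-12, abs=1e-12)


def test_rpos_bounded_on_random_genes(cfg, rng):
    """RPOS stays in [0,1] on random genes including degenerate ones."""
    for _ in range(2000):
        n = int(rng.integers(6, 60))
        labels = random_labels(rng, n)
        kind = rng.integers(0, 4)
        if kind == 0:
            row = np.full(n, float(rng.normal()))  # constant gene
        elif kind == 1:
            row = rng.normal(size=n) + 100 * labels  # zero overlap
        else:
            row = rng.normal(scale=rng.uniform(0.1, 10), size=n)
        rec, _ = score_gene(row, labels, cfg)
        assert 0.0 <= rec.rpos <= 1.0


def test_median_rpos_decreases_with_effect_size(cfg):
    """Planted class-mean shift makes genes more discriminative: the
    median score over 200 informative genes falls as delta grows."""
    rng = np.random.default_rng(2024)
    n = 50
    labels = np.array([0] * n + [1] * n)
    medians = []
    for delta in (0.0, 1.0, 2.0, 4.0):
        Z = rng.normal(size=(200, 2 * n))
        Z[:, n:] += delta
        data = make_data(Z, labels)
        recs, _ = score_all_genes(data, cfg)
        medians.append(np.median([r.rpos for r in recs]))
    assert all(a > b for a, b in zip(medians, medians[1:]))
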