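import numpy as np
import pytest

from slidefactors.expression import ExpressionMatrix, normalize_expression
from slidefactors.groups import (
    discover_groups,
    group_composition,
    infer_status,
    match_statuses,
    state_similarity,
    tc_curve,
)
from slidefactors.synthetic import SynthExpressionConfig, generate_expression


@pytest.fixture(scope="module")
def planted_model(planted_matrix):
    return discover_groups(planted_matrix, n_groups=3, n_iterations=100, seed=0)


class TestDiscoverGroups:
    def test_recovers_planted_statuses(self, planted_model, planted_expression):
        _, agreement, _ = match_statuses(
            planted_model.statuses, planted_expression.statuses
        )
        assert (agreement >= 0.95).all()

    def test_planted_genes_outrank_background(
        self, planted_model, planted_expression
    ):
        mapping, _, _ = match_statuses(
            planted_model.statuses, planted_expression.statuses
        )
        gene_ids = np.array(planted_model.gene_ids)
        for true_k in range(planted_expression.statuses.shape[1]):
            k = mapping[true_k]
            planted = np.array([
                true_k in planted_expression.memberships[g] for g in gene_ids
            ])
            background = np.array([g.startswith("BG") for g in gene_ids])
            assert planted_model.mi[planted, k].min() > \
                planted_model.mi[background, k].max()

    def test_model_invariants(self, planted_model):
        assert set(np.unique(planted_model.statuses)) <= {0, 1}
        assert (planted_model.mi >= 0).all()
        assert (planted_model.tc >= 0).all()
        assert (np.diff(planted_model.tc) <= 1e-12).all()  # non-increasing

    def test_bitwise_reproducible(self, planted_matrix):
        a = discover_groups(planted_matrix, 3, n_iterations=20, seed=7)
        b = discover_groups(planted_matrix, 3, n_iterations=20, seed=7)
        assert np.array_equal(a.statuses, b.statuses)
        assert np.array_equal(a.mi, b.mi)
        assert np.array_equal(a.tc, b.tc)

    def test_perfectly_redundant_genes(self, rng):
        # every gene is an exact copy of one binary pattern
        pattern = (rng.random(80) < 0.5).astype(float)
        values = np.tile(pattern[:, None], (1, 10)) + 0.0
        mat = normalize_expression(values, already_log2=True)
        model = discover_groups(mat, n_groups=1, seed=0)
        agree = (model.statuses[:, 0] == pattern).mean()
        assert agree in (0.0, 1.0)  # equal up to global polarity
        assert model.tc[0] > 0

    def test_too_many_groups_rejected(self, planted_matrix):
        with pytest.raises(ValueError):
            discover_groups(planted_matrix, planted_matrix.n_genes + 1)

    def test_permutation_destroys_tc(self, planted_matrix):
        # independently permuting each gene column kills every group's TC
        rng = np.random.default_rng(3)
        structured_tc = discover_groups(planted_matrix, 3, 30, seed=0).tc.min()
        null_tcs = []
        for rep in range(5):
            perm = np.column_stack([
                rng.permutation(planted_matrix.values[:, j])
                for j in range(planted_matrix.n_genes)
            ])
            m = discover_groups(
                ExpressionMatrix(planted_matrix.sample_ids,
                                 planted_matrix.gene_ids, perm),
                3, 30, seed=0,
            )
            null_tcs.extend(m.tc)
        bound = np.percentile(null_tcs, 95)
        assert max(null_tcs) <= structured_tc  # permuted fits never beat signal
        assert bound < 0.1 * structured_tc


class TestInferStatus:
    def test_training_matrix_reproduces_training_statuses(
        self, planted_model, planted_matrix
    ):
        res = infer_status(planted_model, planted_matrix)
        assert np.array_equal(res.statuses, planted_model.statuses)

    def test_idempotent(self, planted_model, planted_matrix):
        a = infer_status(planted_model, planted_matrix).statuses
        b = infer_status(planted_model, planted_matrix).statuses
        assert np.array_equal(a, b)

    def test_fresh_cohort_recovery(self, planted_model, planted_expression):
        cfg = planted_expression.config
        fresh = generate_expression(
            SynthExpressionConfig(**{**cfg.__dict__, "seed": 123})
        )
        mat = normalize_expression(fresh.matrix.to_frame(), already_log2=True)
        res = infer_status(planted_model, mat)
        _, agreement, _ = match_statuses(res.statuses, fresh.statuses)
        assert (agreement >= 0.95).all()
        assert not res.unreliable_groups.any()

    def test_missing_genes_flag_unreliable_groups(
        self, planted_model, planted_matrix
    ):
        # drop >50% of one group's member genes
        k = 0
        members = np.array(planted_model.gene_ids)[planted_model.assignment == k]
        keep = [g for g in planted_matrix.gene_ids
                if g not in set(members[: int(0.8 * len(members))])]
        res = infer_status(planted_model, planted_matrix.subset_genes(keep))
        assert res.unreliable_groups[k]
        assert len(res.missing_gene_ids) > 0


class TestGroupComposition:
    def test_threshold_too_high_gives_empty_list(self, planted_model):
        comp = group_composition(planted_model, 0, mi_threshold=1e6)
        assert comp.genes == []

    def test_planted_genes_occupy_top_ranks(
        self, planted_model, planted_expression
    ):
        mapping, _, _ = match_statuses(
            planted_model.statuses, planted_expression.statuses
        )
        gpf = planted_expression.config.genes_per_factor
        for true_k in range(3):
            comp = group_composition(planted_model, mapping[true_k])
            top = {g for g, _, _ in comp.genes[:gpf]}
            planted = {
                g for g, ks in planted_expression.memberships.items()
                if true_k in ks
            }
            assert top == planted

    def test_sorted_capped_and_directed(self, planted_model):
        comp = group_composition(planted_model, 0, max_genes=5, mi_threshold=0.002)
        assert len(comp.genes) <= 5
        mis = [mi for _, mi, _ in comp.genes]
        assert mis == sorted(mis, reverse=True)
        assert all(mi > 0.002 for mi in mis)
        assert all(d in (-1, 0, 1) for _, _, d in comp.genes)

    def test_group_id_out_of_range(self, planted_model):
        with pytest.raises(ValueError):
            group_composition(planted_model, 99)


class TestTcCurve:
    def test_noise_tc_below_permutation_bound(self, rng):
        noise = normalize_expression(rng.normal(size=(150, 60)),
                                     already_log2=True)
        curve = tc_curve(noise, [2, 4], n_iterations=20, seed=0)
        # permutation null on the same data: noise permuted is still noise
        null = []
        for rep in range(3):
            perm = np.column_stack([
                rng.permutation(noise.values[:, j]) for j in range(60)
            ])
            pm = ExpressionMatrix(noise.sample_ids, noise.gene_ids, perm)
            null.extend(t for _, t in tc_curve(pm, [2, 4], 20, seed=0))
        bound = np.percentile(null, 95) + 0.5
        assert all(t <= bound for _, t in curve)

    def test_total_tc_non_decreasing_in_d(self, planted_matrix):
        curve = tc_curve(planted_matrix, [1, 2, 3, 4], n_iterations=30, seed=0)
        totals = [t for _, t in curve]
        # adding factors cannot explain less, up to optimiser noise
        assert all(b >= a - 1.0 for a, b in zip(totals, totals[1:]))

    def test_plateau_at_planted_dimension(self, planted_matrix):
        curve = dict(tc_curve(planted_matrix, [3, 5], n_iterations=30, seed=0))
        assert curve[5] <= curve[3] * 1.05  # plateau past the true d

    def test_empty_grid_rejected(self, planted_matrix):
        with pytest.raises(ValueError):
            tc_curve(planted_matrix, [])


class TestStateSimilarity:
    @pytest.mark.parametrize(
        "pred,truth,expected",
        [
            ([1, 0, 1, 1], [1, 0, 1, 1], 1.0),
            ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),
            ([1, 1, 0, 0], [1, 0, 1, 0], 0.5),
        ],
    )
    def test_known_values(self, pred, truth, expected):
        assert state_similarity(pred, truth) == pytest.approx(expected)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            state_similarity([0, 0], [1, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            state_similarity([1, 0], [1, 0, 1])
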