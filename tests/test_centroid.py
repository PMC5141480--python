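"""Centroid construction, concordance, ClaNC selection/classification oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from subtypekit import (
    CentroidModel,
    CohortConfig,
    DataError,
    ExpressionMatrix,
    apply_batch,
    apply_perturbation,
    build_centroids,
    build_clanc_model,
    classify_clanc,
    classify_matrix,
    consensus_call,
    correlate_centroids,
    select_genes_clanc,
    shift_score,
    simulate_expression_cohort,
)
from subtypekit.subtype import preprocess


def em(values, samples=None):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, "log2")


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_centroids(values, labels_by_col, classes):
    """Plain-python evaluation of per-class means and pooled within-class sd."""
    G, n = values.shape
    centroid = {}
    for k in classes:
        cols = [j for j, lab in enumerate(labels_by_col) if lab == k]
        centroid[k] = [sum(values[g][j] for j in cols) / len(cols) for g in range(G)]
    pooled = []
    for g in range(G):
        ss = 0.0
        for k in classes:
            cols = [j for j, lab in enumerate(labels_by_col) if lab == k]
            ss += sum((values[g][j] - centroid[k][g]) ** 2 for j in cols)
        pooled.append(math.sqrt(ss / (n - len(classes))))
    return centroid, pooled


def oracle_distances(x, centroid, pooled_sd, s0):
    out = {}
    for k, c in centroid.items():
        out[k] = sum((xi - ci) ** 2 / (sd + s0) ** 2
                     for xi, ci, sd in zip(x, c, pooled_sd))
    return out


class TestBuildCentroids:
    def test_single_sample_class_is_that_sample(self):
        m = em([[1.0, 5, 5], [2, 8, 8]])
        model = build_centroids(m, {"s0": "luminal", "s1": "basal", "s2": "basal"})
        li = model.classes.index("luminal")
        assert np.array_equal(model.centroid[li], m.values[:, 0])

    def test_zero_spread_engages_s0_fallback(self):
        m = em([[0.0, 0, 2, 2], [0, 0, 2, 2]])
        labels = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        model = build_centroids(m, labels)
        assert np.array_equal(model.pooled_sd, [0.0, 0.0])
        assert model.s0 == 1e-6

    def test_matches_brute_force(self, rng):
        values = rng.normal(size=(3, 4))
        labels_by_col = ["a", "a", "b", "b"]
        m = em(values)
        model = build_centroids(m, dict(zip(m.sample_ids, labels_by_col)))
        ocent, opooled = oracle_centroids(values, labels_by_col, ["a", "b"])
        for k in ("a", "b"):
            assert np.allclose(model.centroid[model.classes.index(k)], ocent[k])
        assert np.allclose(model.pooled_sd, opooled)
        assert model.s0 == pytest.approx(float(np.median(opooled)))

    def test_empty_class_and_degenerate_n_fatal(self):
        m = em(np.ones((2, 2)) + np.eye(2))
        with pytest.raises(DataError):
            build_centroids(m, {"s0": "a", "s1": "a", "sX": "b"})
        with pytest.raises(DataError, match="pooled"):
            build_centroids(m, {"s0": "a", "s1": "b"})


class TestCorrelateCentroids:
    def _model(self, vec, classes=("luminal",)):
        vec = np.atleast_2d(np.asarray(vec, dtype=float))
        genes = [f"g{i}" for i in range(vec.shape[1])]
        return CentroidModel(list(classes), genes, vec, np.ones(vec.shape[1]),
                             0.1, {c: 3 for c in classes})

    def test_identical_vectors_rho_one(self):
        a = self._model([1.0, 2, 3, 4, 5])
        rho, p, n = correlate_centroids(a, a, ("luminal", "luminal"), method="t")
        assert rho == pytest.approx(1.0) and n == 5

    def test_reversed_ranks_rho_minus_one(self):
        a = self._model([1.0, 2, 3, 4, 5])
        b = self._model([5.0, 4, 3, 2, 1])
        rho, _, _ = correlate_centroids(a, b, method="t")
        assert rho == pytest.approx(-1.0)

    def test_matches_scipy_spearman_t_approximation(self, rng):
        a = self._model(rng.normal(size=20))
        b = self._model(rng.normal(size=20))
        rho, p, _ = correlate_centroids(a, b, method="t")
        ref_rho, ref_p = stats.spearmanr(a.centroid[0], b.centroid[0])
        assert rho == pytest.approx(float(ref_rho), abs=1e-12)
        assert p == pytest.approx(float(ref_p), abs=1e-12)

    def test_exact_permutation_p_matches_enumeration(self, rng):
        a = self._model([3.0, 1, 4, 1.5, 9])
        b = self._model([2.0, 7, 1, 8, 2.5])
        rho, p, n = correlate_centroids(a, b, method="exact")
        ra, rb = stats.rankdata(a.centroid[0]), stats.rankdata(b.centroid[0])
        hits = sum(abs(np.corrcoef(ra, rb[list(perm)])[0, 1]) >= abs(rho) - 1e-12
                   for perm in itertools.permutations(range(n)))
        assert p == pytest.approx(hits / math.factorial(n))

    def test_too_few_shared_genes_fatal(self):
        a = self._model([1.0, 2, 3])
        b = CentroidModel(["luminal"], ["h1", "h2", "h3"],
                          np.array([[1.0, 2, 3]]), np.ones(3), 0.1, {"luminal": 3})
        with pytest.raises(DataError, match="shared genes"):
            correlate_centroids(a, b)


class TestSelectGenes:
    def test_balance_contract(self):
        c = simulate_expression_cohort(CohortConfig(
            n_genes=30, n_marker_per_class=8, n_luminal=6, n_basal=6,
            n_nontype=0, seed=5))
        m = preprocess(c.matrix, c.marker_truth)
        sel = select_genes_clanc(m, c.true_labels, 4)
        assert len(sel) == 4
        assert sel["class"].value_counts().to_dict() == {"luminal": 2, "basal": 2}

    def test_zero_d_gene_never_beats_informative_gene(self):
        # g2/g3 identical class means -> d = 0
        vals = np.array([[1.0, 1.2, -1.0, -0.8],
                         [-0.9, -1.1, 1.0, 1.1],
                         [0.5, 0.4, 0.5, 0.4],
                         [0.0, 0.1, 0.0, 0.1]])
        m = em(vals)
        labels = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        sel = select_genes_clanc(m, labels, 2)
        assert set(sel["gene"]) == {"g0", "g1"}

    def test_d_statistic_matches_brute_force(self, rng):
        values = rng.normal(size=(6, 8))
        labels_by_col = ["a"] * 4 + ["b"] * 4
        m = em(values)
        labels = dict(zip(m.sample_ids, labels_by_col))
        sel = select_genes_clanc(m, labels, 6).set_index("gene")
        ocent, opooled = oracle_centroids(values, labels_by_col, ["a", "b"])
        s0 = float(np.median(opooled))
        n = 8
        for gi, g in enumerate(m.gene_ids):
            overall = values[gi].mean()
            expected = {}
            for k, nk in (("a", 4), ("b", 4)):
                mk = math.sqrt(1 / nk - 1 / n)
                expected[k] = (ocent[k][gi] - overall) / (mk * (opooled[gi] + s0))
            # near-ties in |d| (exact for balanced two-class designs) go to
            # the class where the gene is up
            amax = max(abs(d) for d in expected.values())
            tol = 1e-9 * max(1.0, amax)
            tied = [k for k, d in expected.items() if abs(d) >= amax - tol]
            best = max(tied, key=lambda k: (expected[k], k))
            assert sel.loc[g, "class"] == best
            assert sel.loc[g, "d"] == pytest.approx(expected[best], rel=1e-9)

    def test_class_below_two_samples_fatal(self):
        m = em(np.arange(8.0).reshape(2, 4))
        with pytest.raises(DataError):
            select_genes_clanc(m, {"s0": "a", "s1": "b", "s2": "b", "s3": "b"}, 2)


class TestClassify:
    def _toy_model(self):
        return CentroidModel(
            ["basal", "luminal"], ["g0", "g1", "g2"],
            np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]]),
            np.array([0.5, 1.0, 2.0]), 0.5, {"basal": 3, "luminal": 3})

    def test_sample_at_centroid(self):
        model = self._toy_model()
        call = classify_clanc(model, {"g0": 2.0, "g1": 2.0, "g2": 2.0}, "q")
        assert call.label == "luminal"
        assert call.distances["luminal"] == 0.0
        assert call.shift > 0

    def test_midpoint_is_ambiguous(self):
        model = self._toy_model()
        call = classify_clanc(model, {"g0": 1.0, "g1": 1.0, "g2": 1.0})
        assert call.label == "ambiguous"
        assert call.distances["luminal"] == pytest.approx(call.distances["basal"])

    def test_distances_match_brute_force(self, rng):
        model = self._toy_model()
        x = rng.normal(size=3)
        call = classify_clanc(model, dict(zip(model.selected_genes, x)))
        oracle = oracle_distances(
            x, {"basal": model.centroid[0], "luminal": model.centroid[1]},
            model.pooled_sd, model.s0)
        for k in ("basal", "luminal"):
            assert call.distances[k] == pytest.approx(oracle[k], rel=1e-12)

    def test_random_small_models_match_brute_force(self, rng):
        for _ in range(200):
            n_genes = int(rng.integers(1, 6))
            n_classes = int(rng.integers(2, 4))
            classes = [f"c{i}" for i in range(n_classes)]
            model = CentroidModel(
                classes, [f"g{i}" for i in range(n_genes)],
                rng.normal(size=(n_classes, n_genes)),
                rng.uniform(0.1, 2.0, n_genes), float(rng.uniform(0.01, 1.0)),
                {c: 3 for c in classes})
            x = rng.normal(size=n_genes)
            call = classify_clanc(model, dict(zip(model.selected_genes, x)))
            oracle = oracle_distances(
                x, {k: model.centroid[i] for i, k in enumerate(classes)},
                model.pooled_sd, model.s0)
            best = min(sorted(oracle), key=lambda k: oracle[k])
            for k in classes:
                assert call.distances[k] == pytest.approx(oracle[k], rel=1e-9)
            if call.label != "ambiguous":
                assert call.label == best

    def test_missing_genes_tolerated_to_twenty_percent(self):
        model = CentroidModel(
            ["basal", "luminal"], [f"g{i}" for i in range(5)],
            np.vstack([np.zeros(5), np.ones(5)]),
            np.ones(5), 0.5, {"basal": 3, "luminal": 3})
        profile = {f"g{i}": 1.0 for i in range(4)}   # 80% coverage: allowed
        call = classify_clanc(model, profile)
        assert call.label == "luminal"
        with pytest.raises(DataError, match="g3"):
            classify_clanc(model, {f"g{i}": 1.0 for i in range(3)})

    def test_scale_equivariance_of_labels(self, rng):
        c = simulate_expression_cohort(CohortConfig(
            n_genes=40, n_marker_per_class=10, n_luminal=6, n_basal=6,
            n_nontype=0, seed=13))
        m = preprocess(c.matrix, c.marker_truth)
        model1 = build_clanc_model(m, c.true_labels, 10)
        scaled = ExpressionMatrix(m.gene_ids, m.sample_ids, m.values * 3.0, "log2")
        model2 = build_clanc_model(scaled, c.true_labels, 10)
        calls1 = classify_matrix(model1, m)
        calls2 = classify_matrix(model2, scaled)
        assert [c1.label for c1 in calls1] == [c2.label for c2 in calls2]


class TestShiftAndConsensus:
    def _setup(self):
        c = simulate_expression_cohort(CohortConfig(
            n_genes=60, n_marker_per_class=15, n_luminal=10, n_basal=10,
            n_nontype=0, noise_sd=0.0, seed=21))
        m = preprocess(c.matrix, c.marker_truth)
        model = build_clanc_model(m, c.true_labels, 20)
        return c, m, model

    def test_identical_calls_zero_shift(self):
        _, m, model = self._setup()
        call = classify_clanc(model, m.sample_profile("bas001"))
        assert shift_score(model, call, call) == 0.0

    def test_centroid_to_centroid_span(self):
        _, m, model = self._setup()
        li = model.classes.index("luminal")
        bi = model.classes.index("basal")
        lum = classify_clanc(model, dict(zip(model.selected_genes, model.centroid[li])))
        bas = classify_clanc(model, dict(zip(model.selected_genes, model.centroid[bi])))
        span = shift_score(model, lum, bas)
        # d_b(lum) - 0 - (0 - d_l(bas)) = both cross-distances, which are equal
        expected = lum.distances["basal"] + bas.distances["luminal"]
        assert span == pytest.approx(expected)
        assert span > 0

    def test_shift_monotone_in_planted_fraction(self):
        from subtypekit import signature_medians
        c, m, model = self._setup()
        meds = signature_medians(c.matrix, c.marker_truth)
        control = classify_clanc(model, m.sample_profile("bas001"))
        scores = []
        for f in (0.25, 0.5, 0.75, 1.0):
            pert = apply_perturbation(c, ["bas001"], f, "luminal")
            pm = preprocess(pert.matrix, pert.marker_truth, reference_medians=meds)
            call = classify_clanc(model, pm.sample_profile("bas001"))
            scores.append(shift_score(model, call, control))
        assert all(b > a for a, b in zip(scores, scores[1:]))
        assert scores[0] > 0

    def test_model_fingerprint_mismatch_fatal(self):
        _, m, model = self._setup()
        call = classify_clanc(model, m.sample_profile("bas001"))
        other = CentroidModel(["basal", "luminal"], ["gX", "gY"],
                              np.zeros((2, 2)), np.ones(2), 0.5,
                              {"basal": 2, "luminal": 2})
        foreign = classify_clanc(other, {"gX": 0.0, "gY": 0.0})
        with pytest.raises(DataError, match="model"):
            shift_score(model, call, foreign)

    def test_consensus_rules(self):
        def call(label):
            from subtypekit import SubtypeCall
            return SubtypeCall("s", {"luminal": 0.0, "basal": 1.0}, label, 1.0)
        assert consensus_call([call("luminal"), call("luminal")]) == "luminal"
        assert consensus_call([call("luminal"), call("basal")]) == "discordant"
        assert consensus_call([call("ambiguous"), call("luminal")]) == "discordant"
        with pytest.raises(DataError):
            consensus_call([])
        with pytest.raises(DataError):
            consensus_call([call("luminal")])


class TestCrossDatasetConcordance:
    def test_batch_shifted_centroids_same_class_beats_cross_class(self):
        for seed in range(1, 6):
            base = simulate_expression_cohort(CohortConfig(
                n_luminal=20, n_basal=20, n_nontype=0, seed=seed))
            # two datasets sharing templates: independent noise + batch shifts
            from subtypekit import resample_noise
            a = apply_batch(base, 0.5, seed=1000 + seed)
            b = apply_batch(resample_noise(base, seed=500 + seed), 0.5,
                            seed=2000 + seed)
            models = []
            for ds in (a, b):
                sub = ds.matrix.subset_genes(ds.marker_truth.genes())
                models.append(build_centroids(sub, ds.true_labels))
            rho_same, _, _ = correlate_centroids(models[0], models[1],
                                                 ("luminal", "luminal"), method="t")
            rho_cross, _, _ = correlate_centroids(models[0], models[1],
                                                  ("luminal", "basal"), method="t")
            assert rho_same > rho_cross
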