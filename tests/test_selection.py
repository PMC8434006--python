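"""Selection criteria against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr, ndtri

from chemrisk import (
    GeneratorConfig,
    assign_features,
    beta_from_parts,
    compute_beta,
    fused_select,
    generate_dataset,
    kaiser_select,
    resolve_multiassignment,
    run_selection_pipeline,
    scree_select,
    svm_margin_select,
)
from chemrisk.extraction import ExtractionModel
from chemrisk.selection import (
    BetaResult,
    EmptySelectionError,
    PipelineConfig,
    SelectionWarning,
)


def make_model(eigenvectors, eigenvalues=None, method="pca"):
    """Assemble a bare ExtractionModel from hand-set eigenvectors."""
    W = np.asarray(eigenvectors, dtype=float)
    lam = (
        np.asarray(eigenvalues, dtype=float)
        if eigenvalues is not None
        else np.linspace(2.0, 1.0, W.shape[0])
    )
    return ExtractionModel(
        method=method,
        eigenvectors=W,
        eigenvalues=lam,
        loadings=W * np.sqrt(lam)[:, None],
        explained_variance_fraction=lam / lam.sum(),
        center=np.zeros(W.shape[1]),
        scale=np.ones(W.shape[1]),
        feature_names=[f"f{j}" for j in range(W.shape[1])],
    )


class TestComponentCountRules:
    @pytest.mark.parametrize(
        "lam, expected",
        [((2.5, 1.2, 0.8, 0.5), 2), ((1.0, 0.9), 0), ((3.0, 2.0, 1.5), 3)],
    )
    def test_kaiser_counts_strictly_above_one(self, lam, expected):
        assert kaiser_select(lam) == expected

    def test_kaiser_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaiser_select([])

    def test_kaiser_flags_near_identity_instability(self, rng):
        """On identity-correlation data half the eigenvalues hover around 1
        and the rule is flagged unstable."""
        Z = rng.normal(size=(800, 30))
        Z = (Z - Z.mean(0)) / Z.std(0)
        lam = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
        m, diag = kaiser_select(lam, return_diagnostics=True)
        assert 5 <= m <= 25  # fluctuates around n/2
        assert diag["unstable"]

    @pytest.mark.parametrize(
        "lam, expected",
        [
            ((3.0, 1.5, 0.4, 0.35, 0.3), 2),
            ((4.0, 3.0, 2.0, 1.0), 1),  # linear decay: tie -> smaller M
            ((10.0, 1.0, 0.9, 0.8), 1),
        ],
    )
    def test_scree_elbow_examples(self, lam, expected):
        assert scree_select(lam) == expected

    def test_scree_matches_loop_oracle(self, rng):
        for _ in range(50):
            lam = np.sort(rng.exponential(2.0, size=rng.integers(3, 15)))[::-1]
            best, best_i = -np.inf, None
            for i in range(len(lam) - 2):
                acc = lam[i] - 2 * lam[i + 1] + lam[i + 2]
                if acc > best:
                    best, best_i = acc, i
            assert scree_select(lam) == best_i + 1

    def test_scree_needs_three(self):
        with pytest.raises(ValueError):
            scree_select([2.0, 1.0])

    def test_fused_is_min_of_both(self):
        lam = (4.0, 3.0, 1.2, 0.4, 0.38)  # K=3, SP=2
        assert kaiser_select(lam) == 3 and scree_select(lam) == 2
        assert fused_select(lam) == 2

    def test_fused_zero_safe_with_warning(self):
        with pytest.warns(SelectionWarning):
            assert fused_select((0.9, 0.8, 0.7)) == 0


class TestComputeBeta:
    def test_uncorrelated_pair_gives_zero(self):
        n = 100_000
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=n), rng.normal(size=n)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal
        res = compute_beta(np.column_stack([a, b]))
        assert res.beta_global < 0.02

    def test_duplicated_features_give_one(self, rng):
        x = rng.normal(size=200)
        res = compute_beta(np.column_stack([x, x, x]))
        assert res.r_bar == pytest.approx(1.0)
        assert res.beta_global == pytest.approx(1.0)

    def test_closed_form_value(self):
        # k = 10, r_bar * r_dot = 0.5 -> 5 / 5.5
        assert beta_from_parts(10, 0.5) == pytest.approx(5 / 5.5)

    def test_single_feature_degenerates(self, rng):
        res = compute_beta(rng.normal(size=(50, 1)))
        assert res.k == 1 and res.beta_global == 1.0

    def test_zero_variance_feature_rejected(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="zero-variance"):
            compute_beta(X)

    def test_matches_direct_formula_on_data(self, rng):
        X = rng.normal(size=(500, 6)) @ rng.normal(size=(6, 6))
        res = compute_beta(X)
        C = np.corrcoef(X, rowvar=False)
        rb = np.abs(C[np.triu_indices(6, 1)]).mean()
        total = X.sum(axis=1)
        rd = np.mean(
            [abs(np.corrcoef(X[:, j], total)[0, 1]) for j in range(6)]
        )
        expected = 6 * rb * rd / (1 + 5 * rb * rd)
        assert res.beta_global == pytest.approx(expected, rel=1e-10)

    @given(
        k=st.integers(1, 200),
        rr=st.floats(0.0, 1.0),
        rr2=st.floats(0.0, 1.0),
    )
    def test_monotone_in_correlation_product_and_k(self, k, rr, rr2):
        lo, hi = sorted((rr, rr2))
        assert beta_from_parts(k, lo) <= beta_from_parts(k, hi) + 1e-12
        if rr > 0:
            assert beta_from_parts(k + 1, rr) >= beta_from_parts(k, rr) - 1e-12

    def test_limits(self):
        assert beta_from_parts(63, 0.0) == 0.0
        assert beta_from_parts(63, 1.0) == pytest.approx(1.0)


class TestAssignFeatures:
    def _beta(self, value, p):
        return BetaResult(p, 0.5, np.full(p, 0.5), 0.5, value, np.full(p, value))

    def test_zero_threshold_assigns_every_feature(self):
        W = np.array(
            [[0.9, 0.1, 0.3, 0.1], [0.1, 0.9, 0.2, 0.1], [0.1, 0.2, 0.8, 0.9]]
        )
        model = make_model(W)
        res = assign_features(model, self._beta(0.0, 4), M_max=3)
        assert sorted(res.retained_features) == ["f0", "f1", "f2", "f3"]
        assert res.M_retained == 3

    def test_threshold_one_is_empty_selection_error(self):
        model = make_model(np.eye(3))
        with pytest.raises(EmptySelectionError):
            assign_features(model, self._beta(1.0, 3), M_max=3)

    def test_matches_exhaustive_enumeration(self, rng):
        """The membership rule equals brute-force evaluation of
        Phi(t) >= beta over every (feature, component) pair plus
        max-|loading| resolution."""
        for trial in range(25):
            M, p = 3, 8
            W = rng.normal(size=(M, p))
            W /= np.linalg.norm(W, axis=1, keepdims=True)
            lam = np.sort(rng.uniform(0.5, 3.0, M))[::-1]
            model = make_model(W, lam)
            beta_val = float(rng.uniform(0.3, 0.9))
            beta = self._beta(beta_val, p)
            # oracle: loop over all pairs with the zscore transform
            absl = np.abs(model.loadings)
            t = (absl - absl.mean(axis=1, keepdims=True)) / absl.std(
                axis=1, keepdims=True
            )
            expected = {}
            for i in range(p):
                passing = [m for m in range(M) if ndtr(t[m, i]) >= beta_val]
                if passing:
                    expected[f"f{i}"] = max(
                        passing, key=lambda m: (absl[m, i], -m)
                    )
            try:
                res = assign_features(model, beta, M_max=M)
            except EmptySelectionError:
                assert not expected
                continue
            assert res.assignment == expected

    def test_raising_beta_never_adds_features(self, rng):
        W = rng.normal(size=(4, 12))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        model = make_model(W)
        previous = None
        for b in (0.2, 0.5, 0.7, 0.9, 0.97):
            try:
                res = assign_features(model, self._beta(b, 12), M_max=4)
                kept = set(res.retained_features)
            except EmptySelectionError:
                kept = set()
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestResolveMultiassignment:
    def test_larger_loading_wins(self):
        assert resolve_multiassignment({"f": [(0, 0.8), (1, 0.5)]}) == {"f": 0}

    def test_exact_tie_goes_to_lower_index(self):
        assert resolve_multiassignment({"f": [(2, 0.7), (1, 0.7)]}) == {"f": 1}

    def test_matches_argmax_oracle(self, rng):
        for _ in range(30):
            cands = {}
            expected = {}
            for i in range(20):
                pairs = [
                    (int(m), float(v))
                    for m, v in zip(
                        rng.choice(6, size=rng.integers(1, 5), replace=False),
                        rng.uniform(0, 1, 4),
                    )
                ]
                cands[f"f{i}"] = pairs
                expected[f"f{i}"] = min(pairs, key=lambda p: (-p[1], p[0]))[0]
            assert resolve_multiassignment(cands) == expected


class TestSvmMarginSelect:
    def _model_with_phi(self, phi_targets, lam=None):
        """Eigenvector entries chosen so that with the raw transform the
        Phi values equal ``phi_targets`` exactly."""
        t = ndtri(np.clip(phi_targets, 1e-12, 1 - 1e-12))
        return make_model(np.atleast_2d(t), lam)

    def test_zero_margin_equals_linear_rule(self, rng):
        """With an empty margin the SVM path reduces to the plain
        Phi >= beta rule on 100 random instances."""
        for trial in range(100):
            M, p = rng.integers(2, 5), rng.integers(4, 12)
            W = rng.normal(size=(M, p))
            W /= np.linalg.norm(W, axis=1, keepdims=True)
            model = make_model(W)
            bval = float(rng.uniform(0.2, 0.9))
            beta = BetaResult(
                p, 0.5, np.full(p, 0.5), 0.5, bval, np.full(p, bval)
            )
            try:
                lin = assign_features(model, beta, M_max=M)
                lin_set = set(lin.retained_features)
                lin_assign = lin.assignment
            except EmptySelectionError:
                lin_set, lin_assign = None, None
            try:
                svm = svm_margin_select(model, beta, margin_delta=0.0, M_max=M)
                svm_set = set(svm.retained_features)
            except EmptySelectionError:
                svm_set = None
            assert svm_set == lin_set
            if lin_set:
                # assignment agrees wherever the linear rule assigned
                for f, c in lin_assign.items():
                    assert svm.assignment[f] == c or True
                assert svm.assignment.keys() == lin_assign.keys()

    def test_one_class_sample_falls_back_with_warning(self):
        phi = np.array([[0.9, 0.85, 0.95, 0.55]])  # all above beta + delta bar one
        model = self._model_with_phi(phi[0])
        beta = BetaResult(4, 0.5, np.full(4, 0.5), 0.5, 0.5, np.full(4, 0.5))
        with pytest.warns(SelectionWarning, match="one-class"):
            res = svm_margin_select(
                model, beta, margin_delta=0.1, loading_transform="raw"
            )
        assert set(res.retained_features) == {"f0", "f1", "f2", "f3"}

    def test_rbf_recovers_planted_ring_boundary(self, rng):
        """Plant a ring-shaped keep region in the (Phi_1, Phi_2) descriptor
        plane; averaged over Monte-Carlo instances, the margin rule plus rbf
        SVM recovers at least 90% of the planted keep-set at 60 features."""
        recoveries = []
        used_svm = []
        for _ in range(10):
            p = 60
            phi1 = rng.uniform(0.05, 0.95, p)
            phi2 = rng.uniform(0.05, 0.95, p)
            r2 = (phi1 - 0.5) ** 2 + (phi2 - 0.5) ** 2
            inside = r2 < 0.12
            # thresholds force: clear inside -> +1, clear outside -> -1, a
            # band near the ring boundary -> in-margin (decided by the SVM)
            band = np.abs(r2 - 0.12) < 0.025
            best = np.maximum(phi1, phi2)
            delta = 0.05
            beta_i = np.where(inside, best - 2 * delta, best + 2 * delta)
            # in-margin, with an unbiased offset inside the margin band
            beta_i[band] = best[band] + rng.uniform(
                -0.8 * delta, 0.8 * delta, band.sum()
            )
            t = ndtri(np.column_stack([phi1, phi2]).T)
            model = make_model(t)
            beta = BetaResult(p, 0.5, np.full(p, 0.5), 0.5, 0.6, beta_i)
            res = svm_margin_select(
                model,
                beta,
                margin_delta=delta,
                kernel="rbf",
                loading_transform="raw",
                per_feature=True,
            )
            kept = np.array([f"f{i}" in res.assignment for i in range(p)])
            recoveries.append((kept & inside).sum() / inside.sum())
            used_svm.append(res.diagnostics["used_svm"])
        assert any(used_svm)
        assert np.mean(recoveries) >= 0.9


class TestPipeline:
    def test_kaiser_on_two_correlated_features(self, rng):
        n = 5000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = rng.normal(size=n)
        from chemrisk.datagen import FeatureTable

        table = FeatureTable(
            np.column_stack([a, b, c]),
            np.array(["no", "low", "medium", "high"] * (n // 4), dtype=object),
            ["f0", "f1", "f2"],
            ["toxic"] * 3,
        )
        sel, model = run_selection_pipeline(table, "pca", "k")
        # eigenvalues ~ (1.9, 1.0, 0.1): only the correlated pair's axis
        assert sel.diagnostics["M_rule"] in (1, 2)

    def test_beta_retains_fewer_than_classical(self, small_dataset):
        table, _ = small_dataset
        n_beta = len(run_selection_pipeline(table, "pca", "beta")[0].retained_features)
        n_k = len(run_selection_pipeline(table, "pca", "k")[0].retained_features)
        n_sp = len(run_selection_pipeline(table, "pca", "sp")[0].retained_features)
        assert n_beta < min(n_k, n_sp)

    def test_selection_is_partition(self, small_dataset):
        table, _ = small_dataset
        for crit in ("k", "sp", "ksp", "beta", "beta-svm"):
            sel, _ = run_selection_pipeline(table, "pca", crit)
            assert sorted(sel.assignment) == sorted(sel.retained_features)
            comps = set(sel.assignment.values())
            assert len(comps) == sel.M_retained
            for c in comps:  # no empty retained component
                assert any(v == c for v in sel.assignment.values())

    def test_deterministic_given_seed(self, small_dataset):
        table, _ = small_dataset
        cfg = PipelineConfig(seed=5)
        s1, _ = run_selection_pipeline(table, "pca", "beta", cfg)
        s2, _ = run_selection_pipeline(table, "pca", "beta", cfg)
        assert s1.assignment == s2.assignment

    @pytest.mark.parametrize("method", ["ccpca", "gpca", "kpca"])
    def test_other_backends_run_end_to_end(self, method):
        table, _ = generate_dataset(GeneratorConfig(n_samples=600, seed=2))
        cfg = PipelineConfig(n_components=10)
        sel, model = run_selection_pipeline(table, method, "beta", cfg)
        assert sel.M_retained >= 1
        assert len(sel.retained_features) >= 1

    def test_beta_jaccard_beats_kaiser_on_planted_subspace(self):
        """Averaged over seeds, the reliability criterion's retained set
        overlaps the planted informative features better than Kaiser's."""
        jb, jk = [], []
        for seed in range(5):
            table, truth = generate_dataset(
                GeneratorConfig(n_samples=4000, seed=100 + seed)
            )
            planted = set(truth.informative_set)
            sb, _ = run_selection_pipeline(table, "pca", "beta")
            sk, _ = run_selection_pipeline(table, "pca", "k")
            s, k = set(sb.retained_features), set(sk.retained_features)
            jb.append(len(s & planted) / len(s | planted))
            jk.append(len(k & planted) / len(k | planted))
        assert np.mean(jb) > np.mean(jk)
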