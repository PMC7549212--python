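"""Trait matrix, PCA, distances, correlations, ANOVA and Holm-Sidak."""

import numpy as np
import pandas as pd
import pytest

from salipheno.stats import (TRAIT_COLUMNS, build_trait_matrix,
                             compact_letters, holm_sidak, pc_distance,
                             pca, pearson_matrix, two_way_anova)


# -- trait matrix -------------------------------------------------------------

def _records(cells, reps=2):
    rows = []
    rng = np.random.default_rng(0)
    for (pop, treat), base in cells.items():
        for r in range(reps):
            row = {"population": pop, "treatment_mM": treat, "replicate": r}
            row.update({c: base + i + 0.1 * r
                        for i, c in enumerate(TRAIT_COLUMNS)})
            rows.append(row)
    return pd.DataFrame(rows)


def test_trait_matrix_cell_means_and_labels():
    df = pd.DataFrame({
        "population": ["C", "C", "I"],
        "treatment_mM": [0, 0, 0],
        **{c: [10.0, 20.0, 7.0] for c in TRAIT_COLUMNS}})
    m = build_trait_matrix(df)
    assert list(m.index) == ["C0", "I0"]
    assert m.loc["C0", "A"] == 15.0
    assert m.loc["I0", "FD"] == 7.0


def test_trait_matrix_rejects_missing():
    df = pd.DataFrame({"population": ["C"], "treatment_mM": [0],
                       **{c: [1.0] for c in TRAIT_COLUMNS[:-1]}})
    with pytest.raises(ValueError, match="lack variables"):
        build_trait_matrix(df)


def test_default_cohort_matrix_is_10_by_12(default_bundle):
    assert default_bundle.trait_matrix.shape == (10, 12)


# -- PCA ----------------------------------------------------------------------

def power_iteration_eigs(C, n_iter=10_000, tol=1e-14):
    """Independent oracle: power iteration with deflation."""
    C = C.copy()
    eigs = []
    for _ in range(C.shape[0]):
        v = np.ones(C.shape[0]) / np.sqrt(C.shape[0])
        lam = 0.0
        for _ in range(n_iter):
            w = C @ v
            norm = np.linalg.norm(w)
            if norm < tol:
                break
            v_new = w / norm
            if np.linalg.norm(v_new - v) < tol:
                v = v_new
                break
            v = v_new
        lam = float(v @ C @ v)
        eigs.append(lam)
        C = C - lam * np.outer(v, v)
    return np.array(sorted(eigs, reverse=True))


def test_pca_eigenvalues_match_power_iteration_oracle():
    X = pd.DataFrame([[2.0, 1.0, 0.5],
                      [4.0, 2.5, 1.0],
                      [6.0, 2.0, 3.5],
                      [8.0, 5.0, 2.0]], columns=["u", "v", "w"])
    result = pca(X)
    Z = (X - X.mean()) / X.std(ddof=1)
    C = (Z.to_numpy().T @ Z.to_numpy()) / (len(X) - 1)
    expected = power_iteration_eigs(C)
    assert np.allclose(result.eigenvalues, expected, atol=1e-8)
    assert result.variance_pct.sum() == pytest.approx(100.0, abs=1e-6)


def test_collinear_data_loads_everything_on_pc1():
    x = np.arange(10, dtype=float)
    X = pd.DataFrame({"x": x, "y": 2 * x + 1})
    result = pca(X)
    assert result.variance_pct[0] == pytest.approx(100.0)


def test_spherical_data_eigenvalues_near_one(rng):
    X = pd.DataFrame(rng.normal(size=(5000, 4)),
                     columns=list("abcd"))
    result = pca(X)
    assert np.allclose(result.eigenvalues, 1.0, atol=0.1)


def test_pca_reconstruction_and_eigenvalue_sum(rng):
    X = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
    result = pca(X)
    Z = (X - X.mean()) / X.std(ddof=1)
    recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
    assert np.allclose(recon, Z.to_numpy(), atol=1e-8)
    assert result.eigenvalues.sum() == pytest.approx(5.0)
    # loadings orthonormal
    L = result.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(5), atol=1e-10)


def test_pca_rejects_zero_variance_and_tiny_input():
    with pytest.raises(ValueError, match="zero-variance"):
        pca(pd.DataFrame({"x": [1.0, 2, 3], "y": [5.0, 5, 5]}))
    with pytest.raises(ValueError, match="three rows"):
        pca(pd.DataFrame({"x": [1.0, 2], "y": [0.0, 1]}))


# -- score distances ----------------------------------------------------------

def test_pc_distance_hand_cases():
    assert pc_distance([0, 0, 0], [1, 2, 2]) == pytest.approx(3.0)
    assert pc_distance([1, 1, 1], [2, 3, 3]) == pytest.approx(3.0)
    assert pc_distance([4, 5, 6, 99], [4, 5, 6, -99]) == 0.0  # first 3 only
    with pytest.raises(ValueError):
        pc_distance([1, 2], [3, 4])


def test_pc_distance_is_a_metric(rng):
    pts = rng.normal(size=(30, 3))
    for x, y, z in zip(pts[:10], pts[10:20], pts[20:]):
        assert pc_distance(x, y) == pytest.approx(pc_distance(y, x))
        assert pc_distance(x, x) == 0.0
        assert pc_distance(x, z) <= pc_distance(x, y) + pc_distance(y, z) + 1e-12


# -- Pearson ------------------------------------------------------------------

def test_pearson_hand_dataset_matches_covariance_formula():
    x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
    y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
    df = pd.DataFrame({c: x + i for i, c in enumerate(TRAIT_COLUMNS)})
    df["B"] = y
    r, sig = pearson_matrix(df)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    expected = sxy / np.sqrt(((x - x.mean()) ** 2).sum()
                             * ((y - y.mean()) ** 2).sum())
    assert r.loc["A", "B"] == pytest.approx(expected, abs=1e-12)
    assert r.loc["A", "A"] == 1.0
    # A and S differ by a constant -> r exactly 1 and significant
    assert r.loc["A", "S"] == pytest.approx(1.0)
    assert bool(sig.loc["A", "S"])


def test_pearson_matrix_properties(default_bundle):
    r, sig = pearson_matrix(default_bundle.per_plant)
    arr = r.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 1.0)
    assert np.nanmax(np.abs(arr)) <= 1.0 + 1e-12
    eigs = np.linalg.eigvalsh(arr)
    assert eigs.min() > -1e-10  # positive semidefinite
    assert sig.to_numpy().dtype == bool


def test_pearson_zero_variance_reported_missing():
    df = pd.DataFrame({c: [1.0, 2.0, 3.0, 4.0] for c in TRAIT_COLUMNS})
    df["HP"] = 5.0
    r, sig = pearson_matrix(df)
    assert np.isnan(r.loc["HP", "A"])
    assert not sig.loc["HP", "A"]


# -- Holm-Sidak and letters ---------------------------------------------------

def test_holm_sidak_worked_example():
    adj = holm_sidak([0.01, 0.02, 0.04])
    assert adj == pytest.approx([0.029701, 0.039600, 0.04], abs=1e-6)


def test_holm_sidak_properties(rng):
    p = rng.uniform(size=20)
    adj = holm_sidak(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_compact_letters_insert_absorb():
    letters = compact_letters([0, 200, 400], [(0, 400)])
    assert letters[0] != letters[400]
    assert set(letters[200]) & set(letters[0])
    assert set(letters[200]) & set(letters[400])

    all_same = compact_letters([0, 200, 400], [])
    assert set(all_same.values()) == {"a"}

    all_diff = compact_letters([0, 200], [(0, 200)])
    assert all_diff == {0: "a", 200: "b"}


# -- two-way ANOVA ------------------------------------------------------------

def _design(effect=0.0, noise=0.1, reps=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for pop in ("C", "I"):
        for treat in (0, 400):
            mean = effect if pop == "I" else 0.0
            for r in range(reps):
                rows.append({"population": pop, "treatment_mM": treat,
                             "replicate": r,
                             "y": mean + rng.normal(0, noise)})
    return pd.DataFrame(rows)


def test_anova_overwhelming_population_effect():
    report = two_way_anova(_design(effect=10.0), "y")
    assert report.anova_table.loc["population", "PR(>F)"] < 1e-6
    assert report.between_populations["significant"].all()
    assert (report.between_populations["p_adj"]
            >= report.between_populations["p_raw"] - 1e-15).all()


def test_anova_constant_data_finds_nothing():
    df = _design(effect=0.0, noise=0.0)
    df["y"] = 3.0
    report = two_way_anova(df, "y")
    assert not report.between_populations["significant"].any()
    for pop in ("C", "I"):
        assert set(report.letters[pop].values()) == {"a"}


def test_anova_needs_replication():
    df = _design(reps=1)
    with pytest.raises(ValueError, match=">= 2 replicates"):
        two_way_anova(df, "y")


def test_anova_letters_match_pairwise_pattern(default_bundle):
    report = default_bundle.anova["H"]
    for pop, table in report.within_population.items():
        letters = report.letters[pop]
        for row in table.itertuples():
            shared = set(letters[row.level_1]) & set(letters[row.level_2])
            if row.p_adj < 0.05:
                assert not shared
            else:
                assert shared
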