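"""Multivariate layer: trait matrix, PCA, factorial-score distances,
Pearson correlations and two-way ANOVA with Holm-Sidak comparisons.

The analysis variables are the twelve per-plant measurements A, B, S, H, P,
HP, Cha, Chb, TC, Carot, FD and deltaE. Cell means over replicates (one row
per population x treatment combination) feed a correlation-matrix PCA;
components are retained by the Kaiser criterion (eigenvalue > 1) and
population divergence under a treatment is the Euclidean distance between
the two populations' factorial scores in the first three components.
Per-trait inference is a two-way factorial ANOVA with Holm-Sidak-adjusted
simple-effect comparisons, reported the way the plots annotate them:
compact letters across treatments within each population and asterisks
between populations within each treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TRAIT_COLUMNS",
    "PCAResult",
    "AnovaReport",
    "build_trait_matrix",
    "pca",
    "pc_distance",
    "population_distances",
    "pearson_matrix",
    "holm_sidak",
    "compact_letters",
    "two_way_anova",
    "plot_scores",
]

#: Fixed order of the twelve analysis variables.
TRAIT_COLUMNS = ("A", "B", "S", "H", "P", "HP", "Cha", "Chb", "TC",
                 "Carot", "FD", "deltaE")


def build_trait_matrix(records: pd.DataFrame,
                       traits: Sequence[str] = TRAIT_COLUMNS,
                       population_col: str = "population",
                       treatment_col: str = "treatment_mM") -> pd.DataFrame:
    """Population x treatment cell means of the analysis variables.

    Rows are labelled ``<pop><treatment>`` (C0, I400, ...); every design
    cell must contain at least one replicate with all variables present.
    """
    missing = [t for t in traits if t not in records.columns]
    if missing:
        raise ValueError(f"records lack variables: {missing}")
    if records[list(traits)].isna().any().any():
        raise ValueError("records contain missing variable values")
    grouped = records.groupby([population_col, treatment_col], sort=True)
    cells = grouped[list(traits)].mean()
    cells.index = [f"{p}{t}" for p, t in cells.index]
    return cells


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA: eigenvalues, explained variance, loadings,
    factorial scores and the Kaiser-retained component count."""

    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    loadings: pd.DataFrame       # variables x components
    scores: pd.DataFrame         # rows x components
    retained: int


def pca(matrix: pd.DataFrame, standardise: bool = True) -> PCAResult:
    """PCA by eigendecomposition of the correlation (or covariance) matrix.

    Columns are centred and, with ``standardise``, scaled to unit sample
    variance, so eigenvalues sum to the number of variables and the Kaiser
    eigenvalue > 1 rule applies. Each loading column is oriented so its
    largest-magnitude entry is positive, making scores reproducible across
    eigensolvers.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least three rows")
    sd = X.std(axis=0, ddof=1)
    if standardise and np.any(sd == 0):
        bad = list(matrix.columns[sd == 0])
        raise ValueError(f"zero-variance columns cannot be standardised: {bad}")
    Z = X - X.mean(axis=0)
    if standardise:
        Z = Z / sd
    C = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(p):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp_names = [f"PC{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(eigvec, index=matrix.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec, index=matrix.index, columns=comp_names)
    return PCAResult(
        eigenvalues=eigval,
        variance_pct=100.0 * eigval / eigval.sum(),
        loadings=loadings,
        scores=scores,
        retained=int((eigval > 1.0).sum()),
    )


def pc_distance(scores_1: Sequence[float], scores_2: Sequence[float],
                n_components: int = 3) -> float:
    """Euclidean distance between two factorial-score rows over the first
    ``n_components`` components (the 3-D PCA-space population distance)."""
    a = np.asarray(scores_1, dtype=float)
    b = np.asarray(scores_2, dtype=float)
    if a.size < n_components or b.size < n_components:
        raise ValueError(f"need at least {n_components} score components")
    d = a[:n_components] - b[:n_components]
    return float(np.sqrt((d ** 2).sum()))


def population_distances(result: PCAResult, populations: Sequence[str],
                         treatments: Sequence[int],
                         n_components: int = 3) -> pd.Series:
    """Between-population score distance for every treatment (row labels
    must follow the ``<pop><treatment>`` convention of the trait matrix)."""
    if len(populations) != 2:
        raise ValueError("distances are defined between exactly two populations")
    p1, p2 = populations
    out = {}
    for t in treatments:
        out[t] = pc_distance(result.scores.loc[f"{p1}{t}"],
                             result.scores.loc[f"{p2}{t}"], n_components)
    return pd.Series(out, name="D")


def pearson_matrix(records: pd.DataFrame,
                   traits: Sequence[str] = TRAIT_COLUMNS,
                   alpha: float = 0.05
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r with a two-sided significance mask.

    Significance uses the exact t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom. Pairs involving a zero-variance variable are
    reported as NaN (and not significant).
    """
    X = records[list(traits)].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least three observations per pair")
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rr * np.sqrt((n - 2) / (1.0 - rr ** 2))
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    pvals[np.isinf(tstat)] = 0.0
    np.fill_diagonal(pvals, 0.0)
    sig = (pvals < alpha) & np.isfinite(r)
    np.fill_diagonal(sig, False)
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    sdf = pd.DataFrame(sig, index=traits, columns=traits)
    return rdf, sdf


def holm_sidak(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Raw p-values are sorted ascending; the i-th (1-based) becomes
    1 - (1 - p_i)^(m - i + 1), with a running maximum enforcing
    monotonicity. Returned in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, adj)
        adj_sorted[rank] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def compact_letters(levels: Sequence, significant_pairs: Sequence[Tuple]
                    ) -> Dict:
    """Compact letter display via the insert-and-absorb algorithm.

    Levels sharing a letter are not significantly different. ``levels``
    gives the ordering used both for letter assignment and tie-breaking.
    """
    levels = list(levels)
    columns: List[set] = [set(levels)]
    for a, b in significant_pairs:
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                ca = col - {b}
                cb = col - {a}
                for new in (ca, cb):
                    if new and not any(new <= other for other in columns):
                        columns.append(new)
        # absorb: drop columns that became subsets of others
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
    # deterministic letter order: sort columns by their first level
    def col_key(col):
        return [levels.index(x) for x in sorted(col, key=levels.index)]
    columns.sort(key=col_key)
    letters = {lv: "" for lv in levels}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i)
        for lv in levels:
            if lv in col:
                letters[lv] += letter
    return letters


@dataclass
class AnovaReport:
    """Two-way ANOVA of one trait plus simple-effect comparisons."""

    trait: str
    anova_table: pd.DataFrame                  # factor x (F, p, df, ss)
    within_population: Dict[str, pd.DataFrame]  # pop -> pairwise table
    letters: Dict[str, Dict]                   # pop -> treatment -> letters
    between_populations: pd.DataFrame          # per treatment: p_adj, flag

    def significant_between(self, treatment) -> bool:
        return bool(self.between_populations.loc[treatment, "significant"])


def _pairwise(cells: pd.DataFrame, pairs: List[Tuple], mse: float,
              df_resid: int) -> pd.DataFrame:
    rows = []
    for key1, key2 in pairs:
        m1, n1 = cells.loc[key1, "mean"], cells.loc[key1, "n"]
        m2, n2 = cells.loc[key2, "mean"], cells.loc[key2, "n"]
        se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        if se == 0:
            t = 0.0 if m1 == m2 else np.inf
        else:
            t = (m1 - m2) / se
        p = 2.0 * sps.t.sf(abs(t), df_resid) if np.isfinite(t) else 0.0
        rows.append({"level_1": key1, "level_2": key2,
                     "diff": m1 - m2, "t": t, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_sidak(out["p_raw"].to_numpy()) if len(out) else []
    return out


def two_way_anova(records: pd.DataFrame, trait: str,
                  population_col: str = "population",
                  treatment_col: str = "treatment_mM",
                  alpha: float = 0.05) -> AnovaReport:
    """Full-factorial ANOVA with Holm-Sidak simple-effect comparisons.

    The omnibus model is population * treatment; pairwise simple effects
    (treatments within each population, populations within each treatment)
    use the pooled residual mean square and are adjusted by Holm-Sidak
    within each comparison family. Compact letters summarise the
    treatment-within-population pattern; an asterisk-style flag marks
    treatments where the populations differ.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records[[population_col, treatment_col, trait]].copy()
    df.columns = ["pop", "treat", "y"]
    counts = df.groupby(["pop", "treat"]).size()
    if (counts < 2).any():
        raise ValueError("every design cell needs >= 2 replicates")

    model = smf.ols("y ~ C(pop) * C(treat)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(index={"C(pop)": "population",
                                "C(treat)": "treatment",
                                "C(pop):C(treat)": "interaction",
                                "Residual": "residual"})
    mse = float(anova.loc["residual", "sum_sq"] / anova.loc["residual", "df"])
    df_resid = int(anova.loc["residual", "df"])

    cells = df.groupby(["pop", "treat"])["y"].agg(["mean", "size"])
    cells.columns = ["mean", "n"]
    pops = sorted(df["pop"].unique())
    treats = sorted(df["treat"].unique())

    within: Dict[str, pd.DataFrame] = {}
    letters: Dict[str, Dict] = {}
    for pop in pops:
        pairs = [((pop, t1), (pop, t2))
                 for i, t1 in enumerate(treats) for t2 in treats[i + 1:]]
        table = _pairwise(cells, pairs, mse, df_resid)
        table["level_1"] = [k[1] for k in table["level_1"]]
        table["level_2"] = [k[1] for k in table["level_2"]]
        within[pop] = table
        sig = [(r.level_1, r.level_2) for r in table.itertuples()
               if r.p_adj < alpha]
        letters[pop] = compact_letters(treats, sig)

    between_pairs = [((pops[0], t), (pops[1], t)) for t in treats] \
        if len(pops) == 2 else []
    if between_pairs:
        btable = _pairwise(cells, between_pairs, mse, df_resid)
        btable.index = treats
        between = pd.DataFrame({
            "p_raw": btable["p_raw"], "p_adj": btable["p_adj"],
            "significant": btable["p_adj"] < alpha})
    else:
        between = pd.DataFrame(columns=["p_raw", "p_adj", "significant"])

    return AnovaReport(trait=trait, anova_table=anova,
                       within_population=within, letters=letters,
                       between_populations=between)


def plot_scores(result: PCAResult, path, three_d: bool = False) -> None:
    """Scatter of row factorial scores on PC1/PC2 (or PC1-3), saved as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = result.scores
    fig = plt.figure(figsize=(6, 5))
    if three_d:
        ax = fig.add_subplot(projection="3d")
        ax.scatter(scores["PC1"], scores["PC2"], scores["PC3"])
        for label, row in scores.iterrows():
            ax.text(row["PC1"], row["PC2"], row["PC3"], label, fontsize=8)
        ax.set_zlabel(f"PC3 ({result.variance_pct[2]:.1f}%)")
    else:
        ax = fig.add_subplot()
        ax.scatter(scores["PC1"], scores["PC2"])
        for label, row in scores.iterrows():
            ax.annotate(label, (row["PC1"], row["PC2"]), fontsize=8)
    ax.set_xlabel(f"PC1 ({result.variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.variance_pct[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
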