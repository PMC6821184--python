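"""Differential statistics and PLS-DA/VIP ranking.

Per-species two-sided t-tests (pooled by default) and one-way ANOVA with
Bonferroni adjustment over the tested family; Dunnett's many-to-one
comparison against the control group via a Monte-Carlo max-|t| null;
partial least squares discriminant analysis fitted by NIPALS on autoscaled
data, with variable-importance-in-projection (VIP) scores

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ),

where w_a are the unit-norm predictor weights and SS_a the explained
response sum of squares of component a; mean squared VIP is always 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_stats",
    "dunnett_vs_control",
    "PLSDAModel",
    "plsda_fit",
    "vip_scores",
    "heatmap_matrix",
    "plot_heatmap",
]


def differential_stats(
    values: pd.DataFrame,
    groups: pd.Series,
    control_label: str = "control",
    equal_var: bool = True,
    family: Optional[int] = None,
) -> pd.DataFrame:
    """Per-species differential statistics between patients and controls.

    ``groups`` maps sample to its group label; samples whose label equals
    (or starts with) ``control_label`` form the control arm, all others the
    patient arm. The t-test is two-sided and pooled-variance by default
    (``equal_var=False`` switches to Welch); the one-way ANOVA runs across
    the distinct group labels when more than two exist. Bonferroni
    multiplies raw p by the family size (default: rows tested). Rows with
    zero variance in both arms and equal means get p = 1 and a
    ``degenerate`` flag.
    """
    groups = groups.loc[values.columns]
    is_control = (groups == control_label) | groups.str.startswith(control_label)
    if is_control.sum() < 2 or (~is_control).sum() < 2:
        raise ValueError("need >= 2 samples per arm for variance estimates")
    ctrl = values.loc[:, is_control.to_numpy()]
    pat = values.loc[:, (~is_control).to_numpy()]

    rows = []
    for name in values.index:
        x = ctrl.loc[name].dropna().to_numpy(dtype=float)
        y = pat.loc[name].dropna().to_numpy(dtype=float)
        rec: Dict[str, object] = {
            "species": name,
            "control_mean": x.mean() if len(x) else np.nan,
            "patient_mean": y.mean() if len(y) else np.nan,
            "degenerate": False,
        }
        if len(x) < 2 or len(y) < 2:
            rec.update(fold=np.nan, t_p=np.nan, anova_p=np.nan)
            rows.append(rec)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rec["fold"] = y.mean() / x.mean() if x.mean() != 0 else np.nan
        if x.var() == 0 and y.var() == 0 and x.mean() == y.mean():
            rec.update(t_p=1.0, anova_p=1.0, degenerate=True)
            rows.append(rec)
            continue
        rec["t_p"] = float(
            scipy.stats.ttest_ind(y, x, equal_var=equal_var).pvalue
        )
        labels = groups.unique()
        if len(labels) > 2:
            arms = [
                values.loc[name, (groups == g).to_numpy()].dropna().to_numpy()
                for g in labels
            ]
            arms = [a for a in arms if len(a) >= 2]
            rec["anova_p"] = float(scipy.stats.f_oneway(*arms).pvalue)
        else:
            rec["anova_p"] = rec["t_p"]
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("species")
    m = int(family) if family is not None else int(out["t_p"].notna().sum())
    for col in ("t_p", "anova_p"):
        mask = out[col].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            if family is None and mask.sum() == m:
                adj[mask.to_numpy()] = multipletests(
                    out.loc[mask, col], method="bonferroni"
                )[1]
            else:
                # explicit family size: plain Bonferroni arithmetic
                adj[mask.to_numpy()] = np.minimum(out.loc[mask, col] * m, 1.0)
        out[col.replace("_p", "_p_bonf")] = adj
    return out


def dunnett_vs_control(
    values: pd.DataFrame,
    groups: pd.Series,
    control_label: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett-style many-to-one comparisons against a control group.

    For each row, each non-control group is compared with the control by a
    t statistic on the pooled (ANOVA) error; the family-adjusted p-value is
    P(max_j |T_j| >= |t_obs|) under a Monte-Carlo null that draws the group
    means and the pooled variance from their joint null distribution
    (which reproduces Dunnett's correlation structure exactly). A single
    comparison group reduces to the two-sided two-sample t-test up to
    Monte-Carlo error.
    """
    groups = groups.loc[values.columns]
    labels = list(pd.unique(groups))
    if control_label not in labels:
        raise ValueError(f"control group {control_label!r} absent")
    others = [g for g in labels if g != control_label]
    if not others:
        raise ValueError("need at least one comparison group")
    ns = {g: int((groups == g).sum()) for g in labels}
    if min(ns.values()) < 2:
        raise ValueError("need >= 2 samples per group")
    df_err = sum(ns.values()) - len(labels)

    rng = np.random.default_rng(seed)
    # null draw: group means ~ N(0, 1/n), pooled variance ~ chi2(df)/df
    z0 = rng.standard_normal(n_mc) / np.sqrt(ns[control_label])
    s2 = rng.chisquare(df_err, n_mc) / df_err
    max_abs_t = np.zeros(n_mc)
    for g in others:
        zg = rng.standard_normal(n_mc) / np.sqrt(ns[g])
        tg = (zg - z0) / np.sqrt(s2 * (1 / ns[g] + 1 / ns[control_label]))
        max_abs_t = np.maximum(max_abs_t, np.abs(tg))
    max_abs_t.sort()

    rows = []
    ctrl_mask = (groups == control_label).to_numpy()
    for name in values.index:
        row = values.loc[name]
        arms = {g: row[(groups == g).to_numpy()].dropna() for g in labels}
        if any(len(a) < 2 for a in arms.values()):
            for g in others:
                rows.append(
                    {"species": name, "comparison": g, "t": np.nan,
                     "p_raw": np.nan, "p_dunnett": np.nan}
                )
            continue
        sse = sum(((a - a.mean()) ** 2).sum() for a in arms.values())
        dfe = sum(len(a) for a in arms.values()) - len(labels)
        mse = sse / dfe if dfe > 0 else np.nan
        for g in others:
            denom = np.sqrt(mse * (1 / len(arms[g]) + 1 / len(arms[control_label])))
            if not denom > 0:
                t = np.nan
                p_adj = 1.0 if arms[g].mean() == arms[control_label].mean() else np.nan
                p_raw = p_adj
            else:
                t = (arms[g].mean() - arms[control_label].mean()) / denom
                # P(max|T| >= |t|) from the sorted MC sample
                idx = np.searchsorted(max_abs_t, abs(t), side="left")
                p_adj = (n_mc - idx) / n_mc
                p_raw = 2 * scipy.stats.t.sf(abs(t), dfe)
                p_adj = max(p_adj, p_raw)  # adjusted never below raw
            rows.append(
                {"species": name, "comparison": g, "t": t,
                 "p_raw": p_raw, "p_dunnett": p_adj}
            )
    return pd.DataFrame(rows).set_index(["species", "comparison"])


@dataclass
class PLSDAModel:
    """A fitted PLS-DA model (NIPALS, one-hot response).

    ``weights`` (p x A) are unit-norm predictor weight vectors,
    ``scores`` (n x A) the orthogonal score vectors, ``loadings`` the
    predictor loadings, ``y_loadings`` the response loadings and
    ``explained_y_ss`` the response sum of squares captured per component.
    """

    feature_names: List[str]
    class_labels: List[str]
    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    explained_y_ss: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    total_y_ss: float

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def summary(self) -> pd.DataFrame:
        frac = self.explained_y_ss / self.total_y_ss
        return pd.DataFrame(
            {
                "explained_y_ss": self.explained_y_ss,
                "explained_y_fraction": frac,
                "cumulative_y_fraction": np.cumsum(frac),
            },
            index=pd.Index(
                [f"comp{a + 1}" for a in range(self.n_components)],
                name="component",
            ),
        )


def _autoscale(X: np.ndarray, mode: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if mode == "auto":
        scale = X.std(axis=0, ddof=1)
    elif mode == "pareto":
        scale = np.sqrt(X.std(axis=0, ddof=1))
    elif mode == "center":
        scale = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {mode!r}")
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def plsda_fit(
    X: pd.DataFrame,
    groups: pd.Series,
    n_components: int = 2,
    scaling: str = "auto",
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSDAModel:
    """Fit PLS-DA by NIPALS sequential extraction.

    ``X`` is samples x species; ``groups`` assigns each sample a class
    label, one-hot encoded and centered as the response block. Predictors
    are centered and unit-variance scaled by default. The fit is
    deterministic given input order: no randomness is involved.
    """
    groups = groups.loc[X.index]
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("PLS-DA needs >= 2 groups")
    Y = np.column_stack(
        [(groups == g).to_numpy(dtype=float) for g in labels]
    )
    Y = Y - Y.mean(axis=0)
    Xs, mean, scale = _autoscale(X.to_numpy(dtype=float), scaling)
    if np.isnan(Xs).any():
        raise ValueError("X contains missing values; impute or drop first")
    rank = np.linalg.matrix_rank(Xs)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")

    n, p = Xs.shape
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    ss = np.zeros(n_components)
    total_y_ss = float((Y ** 2).sum())
    Xa, Ya = Xs.copy(), Y.copy()
    for a in range(n_components):
        u = Ya[:, int(np.argmax(Ya.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = Xa.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("degenerate component: zero weight vector")
            w /= norm
            t = Xa @ w
            q = Ya.T @ t / (t @ t)
            u = Ya @ q / (q @ q)
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        p_load = Xa.T @ t / (t @ t)
        ss[a] = float((t @ t) * (q @ q))
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_load, q
        Xa = Xa - np.outer(t, p_load)
        Ya = Ya - np.outer(t, q)
    return PLSDAModel(
        feature_names=list(X.columns),
        class_labels=labels,
        weights=W,
        scores=T,
        loadings=P,
        y_loadings=Q,
        explained_y_ss=ss,
        x_mean=mean,
        x_scale=scale,
        total_y_ss=total_y_ss,
    )


def vip_scores(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection per species.

    Weighted by each component's explained response sum of squares; the
    squared scores average to 1 over species by construction.
    """
    ss = model.explained_y_ss
    if not np.any(ss > 0):
        raise ValueError("model explains no response variance")
    W = model.weights
    wnorm2 = (W ** 2) / (W ** 2).sum(axis=0, keepdims=True)
    p = W.shape[0]
    vip = np.sqrt(p * (wnorm2 @ ss) / ss.sum())
    return pd.Series(vip, index=model.feature_names, name="VIP")


def heatmap_matrix(
    values: pd.DataFrame,
    ranking: pd.Series,
    k: int = 30,
    pseudo_count: Optional[float] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Top-k heat-map matrix: log abundance centered per species.

    Rows are the ``k`` highest-ranked species (by ``ranking``, descending);
    entries are log(value + pseudo-count) minus the species' mean, so color
    reflects abundance above/below each metabolite's own mean. The default
    pseudo-count is half the smallest nonzero value of the matrix.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if not set(values.index) <= set(ranking.index):
        raise ValueError("ranking must cover all species")
    k = min(k, len(values))
    top = ranking.loc[values.index].sort_values(ascending=False).index[:k]
    sub = values.loc[top].to_numpy(dtype=float)
    if pseudo_count is None:
        positive = sub[sub > 0]
        pseudo_count = float(positive.min()) / 2 if len(positive) else 1.0
    logged = np.log(sub + pseudo_count)
    centered = logged - np.nanmean(logged, axis=1, keepdims=True)
    out = pd.DataFrame(centered, index=top, columns=values.columns)
    return out, list(top)


def plot_heatmap(matrix: pd.DataFrame, path=None, cmap: str = "RdBu_r"):
    """Render a heat-map matrix (red above, blue below each species' mean).

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(0.4 * matrix.shape[1] + 3, 0.22 * matrix.shape[0] + 2)
    )
    lim = float(np.nanmax(np.abs(matrix.to_numpy()))) or 1.0
    im = ax.imshow(
        matrix.to_numpy(), aspect="auto", cmap=cmap, vmin=-lim, vmax=lim
    )
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log abundance - species mean")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
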