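"""Stringent two-step selection of process-specific features.

Step 1 screens each feature with a Kruskal–Wallis test between quintiles
1, 3 and 5 of a process (Bonferroni family of 150, adjusted P < 0.001).
Step 2 guards against groups of near-collinear features all passing the
univariate screen: a canonical variate analysis (CVA) of the same three
groups is fitted on the full standardized feature matrix, each feature is
scored by the sum over canonical vectors of its squared load, and only
features in the top half of that ranking are retained.

A feature passing both steps for Cell Speed only, CMD only, or both is
classed ``speed_only`` / ``cmd_only`` / ``both``; everything else is
``neither``.

CVA here is the multi-group canonical discriminant decomposition: with
between-group scatter B and pooled within-group scatter W, the canonical
vectors v solve W⁻¹B v = λ v (at most n_groups − 1 = 2 informative vectors
for three groups), normalized so canonical variates have unit pooled
within-group variance (vᵀWv = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .archetypes import assign_quintiles

__all__ = [
    "CvaModel",
    "SelectionResult",
    "kruskal_wallis",
    "fit_cva",
    "cva_load_scores",
    "classify_features",
    "select_features",
]


def kruskal_wallis(
    samples: list[np.ndarray], family: int = 150
) -> tuple[float, float]:
    """Kruskal–Wallis H-test p-value, raw and Bonferroni-adjusted."""
    samples = [np.asarray(s, float) for s in samples]
    samples = [s[np.isfinite(s)] for s in samples]
    if any(len(s) == 0 for s in samples):
        raise ValueError("each group must be non-empty")
    if all((s == samples[0][0]).all() for s in samples):
        # identical constant groups: no separation
        return 1.0, 1.0
    _, p = stats.kruskal(*samples)
    return float(p), float(min(1.0, p * family))


@dataclass
class CvaModel:
    """Canonical variate decomposition of grouped feature data."""

    feature_names: list[str]
    vectors: np.ndarray  # (n_features, n_vectors), vᵀWv = 1 columns
    eigenvalues: np.ndarray  # descending
    group_labels: np.ndarray
    standardized: bool

    @property
    def loads(self) -> np.ndarray:
        """Per-feature coefficients on each canonical vector."""
        return self.vectors


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw between-group (B) and pooled within-group (W) scatter sums."""
    groups = np.unique(y)
    p = X.shape[1]
    mu = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        Xg = X[y == g]
        mg = Xg.mean(axis=0)
        d = Xg - mg
        W += d.T @ d
        diff = (mg - mu)[:, None]
        B += len(Xg) * (diff @ diff.T)
    return B, W


def fit_cva(
    features: pd.DataFrame,
    groups: np.ndarray,
    standardize: bool = True,
    ridge: float | None = None,
) -> CvaModel:
    """Fit canonical vectors separating the labelled groups.

    Features are centered and scaled to unit variance by default: loads of
    features measured in wildly different units are compared against each
    other downstream, which is only meaningful on a common scale. Rows with
    any missing value are dropped listwise. An ill-conditioned pooled
    within-group scatter is regularized by a small ridge
    (1e−8 · trace(W)/p unless given) with a warning.
    """
    X = features.to_numpy(float)
    y = np.asarray(groups)
    ok = np.isfinite(X).all(axis=1)
    X, y = X[ok], y[ok]
    n_groups = len(np.unique(y))
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    B, W = _scatter_matrices(X, y)
    p = W.shape[0]
    cond = np.linalg.cond(W)
    if ridge is None and (not np.isfinite(cond) or cond > 1e12):
        ridge = 1e-8 * np.trace(W) / p
        warnings.warn(f"within-group scatter ill-conditioned; ridge {ridge:.3g} applied")
    if ridge:
        W = W + ridge * np.eye(p)

    # generalized symmetric-definite eigenproblem B v = λ W v; eigh returns
    # vᵀWv = 1 columns, rescaled so canonical variates have unit pooled
    # within-group variance vᵀWv/(n − g) = 1
    eigvals, eigvecs = linalg.eigh(B, W)
    eigvecs = eigvecs * np.sqrt(len(y) - n_groups)
    order = np.argsort(eigvals)[::-1][: n_groups - 1]
    return CvaModel(
        feature_names=list(features.columns),
        vectors=eigvecs[:, order],
        eigenvalues=eigvals[order],
        group_labels=y,
        standardized=standardize,
    )


def cva_load_scores(model: CvaModel) -> pd.DataFrame:
    """Per-feature importance: sum over canonical vectors of squared loads.

    The top half of features ranked by descending score is flagged;
    features tied with the boundary score are flagged inclusively.
    """
    scores = (model.loads**2).sum(axis=1)
    df = pd.DataFrame({"feature": model.feature_names, "cva_score": scores})
    n_top = int(np.ceil(len(df) / 2))
    threshold = np.sort(scores)[::-1][n_top - 1]
    df["top_half"] = df["cva_score"] >= threshold
    return df.set_index("feature")


@dataclass
class SelectionResult:
    """Outcome of the two-step selection for both processes."""

    per_feature: pd.DataFrame
    class_counts: dict[str, int]
    models: dict[str, CvaModel]


def classify_features(
    kw_speed: pd.Series,
    kw_cmd: pd.Series,
    top_speed: pd.Series,
    top_cmd: pd.Series,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Combine per-process KW significance and CVA top-half flags."""
    feats = kw_speed.index
    pass_speed = (kw_speed < alpha) & top_speed.reindex(feats)
    pass_cmd = (kw_cmd < alpha) & top_cmd.reindex(feats)
    cls = np.where(
        pass_speed & pass_cmd,
        "both",
        np.where(pass_speed, "speed_only", np.where(pass_cmd, "cmd_only", "neither")),
    )
    return pd.DataFrame(
        {
            "kw_p_adj_speed": kw_speed,
            "kw_p_adj_cmd": kw_cmd,
            "top_half_speed": top_speed.reindex(feats),
            "top_half_cmd": top_cmd.reindex(feats),
            "class": cls,
        },
        index=feats,
    )


def select_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    alpha: float = 0.001,
    family: int | None = None,
    standardize: bool = True,
) -> SelectionResult:
    """Run the full two-step Kruskal–Wallis + CVA selection on a table.

    For each process (``cell_speed``, ``cmd``) observations in quintiles
    1, 3 and 5 define three groups; the Bonferroni family defaults to the
    number of features (one KW test each, per process).
    """
    if features is None:
        from .ingest import feature_columns

        features = feature_columns(table)
    if family is None:
        family = len(features)
    valid = table["valid"].to_numpy(bool) if "valid" in table else np.ones(len(table), bool)
    t = table[valid]

    kw: dict[str, pd.Series] = {}
    top: dict[str, pd.Series] = {}
    models: dict[str, CvaModel] = {}
    for process in ("cell_speed", "cmd"):
        q = assign_quintiles(t[process].to_numpy(float))
        keep = np.isin(q, (1, 3, 5))
        sub = t[keep]
        labels = q[keep]
        pvals = {}
        for feat in features:
            x = sub[feat].to_numpy(float)
            _, adj = kruskal_wallis([x[labels == g] for g in (1, 3, 5)], family=family)
            pvals[feat] = adj
        kw[process] = pd.Series(pvals, name=f"kw_{process}")
        model = fit_cva(sub[features], labels, standardize=standardize)
        models[process] = model
        top[process] = cva_load_scores(model)["top_half"]

    per_feature = classify_features(
        kw["cell_speed"], kw["cmd"], top["cell_speed"], top["cmd"], alpha=alpha
    )
    counts = per_feature["class"].value_counts().to_dict()
    class_counts = {
        c: int(counts.get(c, 0)) for c in ("speed_only", "cmd_only", "both", "neither")
    }
    return SelectionResult(per_feature=per_feature, class_counts=class_counts, models=models)
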