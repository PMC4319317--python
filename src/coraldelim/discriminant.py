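"""Canonical discriminant analysis with forward stepping and jackknife.

Given a corallite-by-trait matrix and a grouping (region or species),
this module provides:

* per-trait one-way ANOVA with Tukey HSD post-hoc comparisons;
* canonical discriminant analysis — eigen-decomposition of W^-1 B
  where W and B are the within- and between-group scatter matrices,
  with Wilks' Lambda = prod 1/(1+lambda_i) and Bartlett's chi-square
  approximation for the overall test;
* forward-stepwise variable selection on partial-F for reducing
  Wilks' Lambda (defaults F-to-enter 4.0, F-to-remove 3.9, the
  documented defaults of the classic stepwise discriminant programs);
* leave-one-out (jackknifed) classification to nearest group centroid
  in canonical space with equal priors.

Organised statsmodels-style: ``CanonicalDiscriminant(data, group).fit()``
returns a ``CDAResults``; ``forward_stepwise`` returns a
``StepwiseResults`` that carries the selection path and the final fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "anova_by_trait",
    "CanonicalDiscriminant",
    "CDAResults",
    "forward_stepwise",
    "StepwiseResults",
    "jackknife_classify",
    "ClassificationMatrix",
]


def anova_by_trait(
    data: pd.DataFrame, group: str, traits: list[str] | None = None, alpha: float = 0.05
):
    """One-way ANOVA and Tukey HSD per trait across groups.

    Returns (table, tukey) where ``table`` has one row per trait with
    F, p and a ``degenerate`` flag (zero within-group variance), and
    ``tukey`` maps trait -> the statsmodels Tukey HSD results object.
    """
    if traits is None:
        traits = [c for c in data.columns if c != group and pd.api.types.is_numeric_dtype(data[c])]
    glabels = data[group].unique()
    if len(glabels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    rows, tukey = [], {}
    for t in traits:
        sub = data[[group, t]].dropna()
        samples = [g[t].to_numpy() for _, g in sub.groupby(group)]
        if any(len(s) < 2 for s in samples):
            raise ValueError(f"trait {t!r}: every group needs >=2 observations")
        degenerate = all(np.ptp(s) == 0 for s in samples)
        if degenerate:
            f_val, p_val = np.nan, np.nan
        else:
            f_val, p_val = scipy.stats.f_oneway(*samples)
            tukey[t] = pairwise_tukeyhsd(sub[t], sub[group], alpha=alpha)
        rows.append({"trait": t, "F": f_val, "p": p_val, "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("trait"), tukey


def _scatter(X: np.ndarray, gidx: np.ndarray, n_groups: int):
    """Within- and between-group scatter matrices and group means."""
    mu = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = np.empty((n_groups, p))
    for g in range(n_groups):
        Xg = X[gidx == g]
        means[g] = Xg.mean(axis=0)
        C = Xg - means[g]
        W += C.T @ C
        B += len(Xg) * np.outer(means[g] - mu, means[g] - mu)
    return W, B, means


def _wilks(X: np.ndarray, gidx: np.ndarray, n_groups: int) -> float:
    W, B, _ = _scatter(X, gidx, n_groups)
    sign_w, ld_w = np.linalg.slogdet(W)
    sign_t, ld_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular scatter matrix")
    return float(np.exp(ld_w - ld_t))


@dataclass
class CDAResults:
    """Fitted canonical discriminant analysis."""

    variables: list[str]
    group_labels: list[str]
    eigenvalues: np.ndarray
    coefficients: np.ndarray  # columns = canonical factors (raw, unstandardized)
    wilks_lambda: float
    chi2: float
    df: int
    p_value: float
    centroids: np.ndarray  # groups x factors
    scores: pd.DataFrame = field(repr=False, default=None)
    means_: np.ndarray = field(repr=False, default=None)

    @property
    def n_factors(self) -> int:
        return len(self.eigenvalues)

    def transform(self, X) -> np.ndarray:
        """Project rows (in original variable order) into canonical space."""
        return np.asarray(X, dtype=float) @ self.coefficients

    def classify(self, X) -> np.ndarray:
        """Nearest-centroid group assignment in canonical space (equal priors)."""
        Z = self.transform(X)
        d2 = ((Z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(self.group_labels)[np.argmin(d2, axis=1)]

    def summary(self) -> str:
        lines = [
            "Canonical discriminant analysis",
            f"  groups: {', '.join(map(str, self.group_labels))}",
            f"  variables ({len(self.variables)}): {', '.join(self.variables)}",
            f"  Wilks' Lambda = {self.wilks_lambda:.4f}  "
            f"chi2({self.df}) = {self.chi2:.2f}  p = {self.p_value:.4g}",
            "  eigenvalues: " + " ".join(f"{e:.3f}" for e in self.eigenvalues),
        ]
        return "\n".join(lines)


class CanonicalDiscriminant:
    """Canonical discriminant model over a trait table.

    Parameters
    ----------
    data : DataFrame with one row per corallite
    group : name of the grouping column
    variables : trait columns to use (default: all numeric, non-group)

    Rows with a missing value in any selected variable are dropped with
    a logged count before fitting.
    """

    def __init__(self, data: pd.DataFrame, group: str, variables: list[str] | None = None):
        if variables is None:
            variables = [
                c for c in data.columns
                if c != group and pd.api.types.is_numeric_dtype(data[c])
            ]
        sub = data[[group] + list(variables)]
        n0 = len(sub)
        sub = sub.dropna()
        if len(sub) < n0:
            warnings.warn(f"dropped {n0 - len(sub)} rows with missing trait values")
        self.data = sub
        self.group = group
        self.variables = list(variables)
        self.group_labels = sorted(sub[group].unique())
        if len(self.group_labels) < 2:
            raise ValueError("need at least two groups")
        self._gidx = np.array([self.group_labels.index(g) for g in sub[group]])
        self.X = sub[self.variables].to_numpy(dtype=float)
        n, p, g = len(sub), len(self.variables), len(self.group_labels)
        if n <= p + g:
            raise ValueError(
                f"too few rows ({n}) for {p} variables and {g} groups; reduce variables"
            )

    def fit(self) -> CDAResults:
        X, gidx = self.X, self._gidx
        n, p = X.shape
        g = len(self.group_labels)
        W, B, means = _scatter(X, gidx, g)
        try:
            evals, evecs = scipy.linalg.eigh(B, W)
        except scipy.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular within-group scatter; reduce or decorrelate variables"
            ) from e
        order = np.argsort(evals)[::-1]
        k = min(g - 1, p)
        evals = np.clip(evals[order][:k], 0.0, None)
        A = evecs[:, order][:, :k]
        # scale factors to unit pooled within-group variance
        for j in range(k):
            s = A[:, j] @ (W / (n - g)) @ A[:, j]
            if s > 0:
                A[:, j] /= np.sqrt(s)
        lam = float(np.prod(1.0 / (1.0 + evals)))
        chi2 = -(n - 1 - (p + g) / 2.0) * np.log(lam)
        df = p * (g - 1)
        pval = float(scipy.stats.chi2.sf(chi2, df))
        Z = X @ A
        centroids = np.vstack([Z[gidx == i].mean(axis=0) for i in range(g)])
        scores = pd.DataFrame(
            Z, columns=[f"factor_{j+1}" for j in range(k)], index=self.data.index
        )
        scores[self.group] = self.data[self.group].to_numpy()
        return CDAResults(
            variables=self.variables,
            group_labels=self.group_labels,
            eigenvalues=evals,
            coefficients=A,
            wilks_lambda=lam,
            chi2=float(chi2),
            df=df,
            p_value=pval,
            centroids=centroids,
            scores=scores,
            means_=means,
        )


@dataclass
class StepwiseResults:
    """Forward-stepwise selection path plus the final canonical fit."""

    selected: list[str]
    wilks_path: list[float]
    steps: list[tuple]  # (action, variable, partial_F, wilks)
    final: CDAResults | None

    @property
    def wilks_lambda(self) -> float:
        return self.final.wilks_lambda if self.final else 1.0

    @property
    def empty(self) -> bool:
        return not self.selected

    def summary(self) -> str:
        lines = ["Forward-stepwise canonical discriminant analysis"]
        for action, var, fstat, lam in self.steps:
            lines.append(f"  {action:>6} {var:<8} partial F = {fstat:8.2f}  Lambda = {lam:.4f}")
        if self.final:
            lines.append(self.final.summary())
        else:
            lines.append("  (no variable passed the entry threshold)")
        return "\n".join(lines)


def _partial_f(lam_old: float, lam_new: float, n: int, g: int, p_in: int) -> float:
    """Rao's partial F for changing the model by one variable.

    ``p_in`` is the number of variables already in the smaller model.
    """
    if lam_new <= 0:
        return np.inf
    return (n - g - p_in) / (g - 1) * (lam_old / lam_new - 1.0)


def forward_stepwise(
    data: pd.DataFrame,
    group: str,
    variables: list[str] | None = None,
    f_to_enter: float = 4.0,
    f_to_remove: float = 3.9,
    max_steps: int = 100,
) -> StepwiseResults:
    """Forward-stepwise variable selection for discriminant analysis.

    At each step the candidate maximizing the partial F for reducing
    Wilks' Lambda enters if its F >= f_to_enter; any entered variable
    whose removal F < f_to_remove is then removed. Deterministic:
    identical data and thresholds give an identical path.
    """
    if variables is None:
        variables = [
            c for c in data.columns
            if c != group and pd.api.types.is_numeric_dtype(data[c])
        ]
    sub = data[[group] + list(variables)].dropna()
    glabels = sorted(sub[group].unique())
    g = len(glabels)
    gidx = np.array([glabels.index(x) for x in sub[group]])
    n = len(sub)

    def wilks(vars_):
        if not vars_:
            return 1.0
        return _wilks(sub[list(vars_)].to_numpy(dtype=float), gidx, g)

    selected: list[str] = []
    lam_cur = 1.0
    steps, path = [], []
    for _ in range(max_steps):
        changed = False
        # entry
        best = None
        for v in variables:
            if v in selected:
                continue
            try:
                lam_v = wilks(selected + [v])
            except np.linalg.LinAlgError:
                continue
            f_v = _partial_f(lam_cur, lam_v, n, g, len(selected))
            if best is None or f_v > best[1]:
                best = (v, f_v, lam_v)
        if best is not None and best[1] >= f_to_enter:
            selected.append(best[0])
            lam_cur = best[2]
            steps.append(("enter", best[0], best[1], lam_cur))
            path.append(lam_cur)
            changed = True
        # removal
        if len(selected) > 1:
            worst = None
            for v in selected:
                rest = [x for x in selected if x != v]
                lam_r = wilks(rest)
                f_v = _partial_f(lam_r, lam_cur, n, g, len(rest))
                if worst is None or f_v < worst[1]:
                    worst = (v, f_v, lam_r)
            if worst is not None and worst[1] < f_to_remove:
                selected.remove(worst[0])
                lam_cur = worst[2]
                steps.append(("remove", worst[0], worst[1], lam_cur))
                path.append(lam_cur)
                changed = True
        if not changed:
            break

    final = None
    if selected:
        final = CanonicalDiscriminant(sub, group, selected).fit()
    else:
        warnings.warn("forward stepping selected no variables (empty model)")
    return StepwiseResults(selected, path, steps, final)


@dataclass
class ClassificationMatrix:
    """Jackknifed (leave-one-out) classification counts."""

    counts: pd.DataFrame  # true group (rows) x predicted group (columns)
    skipped: int = 0

    @property
    def pct_correct(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts), index=self.counts.index)
        return 100.0 * diag / self.counts.sum(axis=1)

    @property
    def total_pct_correct(self) -> float:
        return float(100.0 * np.trace(self.counts) / self.counts.to_numpy().sum())

    def summary(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["% correct"] = self.pct_correct.round(0)
        return out


def jackknife_classify(
    data: pd.DataFrame, group: str, variables: list[str]
) -> ClassificationMatrix:
    """Leave-one-out classification with a fixed variable set.

    Each row is held out, the canonical model is refitted on the
    remainder, and the row is assigned to the nearest group centroid in
    canonical space (equal priors). Rows whose removal makes the fit
    singular are skipped with a warning.
    """
    sub = data[[group] + list(variables)].dropna().reset_index(drop=True)
    glabels = sorted(sub[group].unique())
    sizes = sub[group].value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 rows for leave-one-out")
    counts = pd.DataFrame(0, index=glabels, columns=glabels, dtype=int)
    skipped = 0
    for i in range(len(sub)):
        train = sub.drop(index=i)
        try:
            res = CanonicalDiscriminant(train, group, list(variables)).fit()
        except (np.linalg.LinAlgError, ValueError):
            skipped += 1
            warnings.warn(f"row {i}: singular leave-one-out fit, skipped")
            continue
        pred = res.classify(sub.loc[[i], list(variables)].to_numpy(dtype=float))[0]
        counts.loc[sub.loc[i, group], pred] += 1
    return ClassificationMatrix(counts, skipped)
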