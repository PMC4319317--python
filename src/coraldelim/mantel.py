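"""Concordance between genetic and morphological inter-region distances.

The genetic side is the matrix of mean between-region molecular
distances; the morphological side, for one trait, is the absolute
difference of region trait means (region mean = mean of specimen
means). Association is tested with the Mantel permutation test:
Pearson correlation over the n(n-1)/2 off-diagonal pairs, null
distribution from jointly permuting rows and columns of one matrix.
For small n every one of the n! relabellings is enumerated exactly;
otherwise Monte Carlo with the (b+1)/(n+1) rule. The default
alternative is one-sided positive (concordance).

Ordinary least-squares regression of the same pairs is provided for
effect description only; its nominal significance is unreliable for
distance matrices (non-independent pairs), so inference always comes
from the permutation test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdist import DistanceMatrix, GroupDistanceSummary

__all__ = [
    "genetic_region_matrix",
    "morph_region_matrix",
    "MantelTest",
    "MantelResult",
    "mantel_test",
    "regress_matrices",
    "screen_traits",
]

EXHAUSTIVE_LIMIT = 50_000  # enumerate all n! relabellings when n! <= this


def genetic_region_matrix(
    summary: GroupDistanceSummary, regions: list[str] | None = None
) -> DistanceMatrix:
    """Region-level matrix of mean between-region genetic distances."""
    regions = list(regions) if regions is not None else list(summary.groups)
    missing = [r for r in regions if r not in summary.groups]
    if missing:
        raise KeyError(f"regions without distance summaries: {missing}")
    k = len(regions)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = summary.between(regions[i], regions[j])
            if np.isnan(v):
                raise ValueError(f"no between mean for pair ({regions[i]}, {regions[j]})")
            m[i, j] = m[j, i] = v
    return DistanceMatrix(regions, m, {"model": "mean-between-region"})


def morph_region_matrix(
    summaries: pd.DataFrame, trait: str, regions: list[str] | None = None
) -> DistanceMatrix:
    """|difference of region means| matrix for one morphometric trait.

    ``summaries`` is the specimen-level table (specimen_id, region,
    trait, mean, ...); the region mean averages its specimen means.
    """
    sub = summaries[summaries["trait"] == trait].dropna(subset=["mean"])
    if regions is None:
        regions = sorted(sub["region"].unique())
    means = {}
    for r in regions:
        vals = sub.loc[sub["region"] == r, "mean"]
        if vals.empty:
            raise ValueError(f"trait {trait!r} absent in region {r!r}")
        means[r] = float(vals.mean())
    k = len(regions)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = abs(means[regions[i]] - means[regions[j]])
    return DistanceMatrix(list(regions), m, {"model": f"abs-mean-diff:{trait}"})


@dataclass
class MantelResult:
    """Mantel matrix-correlation statistic with permutation p."""

    trait: str
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    method: str  # "exhaustive" or "monte-carlo"
    constant: bool = False

    def summary(self) -> str:
        if self.constant:
            return f"Mantel[{self.trait}]: undefined (a matrix is constant)"
        return (
            f"Mantel[{self.trait}]: r = {self.r:.4f}, r^2 = {self.r_squared:.4f}, "
            f"p = {self.p_value:.4g} ({self.method}, {self.n_permutations} permutations)"
        )


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


class MantelTest:
    """Mantel test model for two labelled distance matrices.

    fit(n_perm, seed, alternative) -> MantelResult. Matrices must share
    the same labels in the same order.
    """

    def __init__(self, m1: DistanceMatrix, m2: DistanceMatrix, trait: str = ""):
        if list(m1.labels) != list(m2.labels):
            raise ValueError("matrices must share identical label order")
        if len(m1) < 3:
            raise ValueError("Mantel test needs at least 3 labels")
        self.m1, self.m2 = m1, m2
        self.trait = trait

    def fit(
        self,
        n_perm: int = 9999,
        seed: int | None = None,
        alternative: str = "greater",
    ) -> MantelResult:
        a = self.m1.values
        b = self.m2.values
        x = _offdiag(a)
        y = _offdiag(b)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("constant distance matrix: Mantel correlation undefined")
            return MantelResult(self.trait, np.nan, np.nan, np.nan, 0, "none", constant=True)

        def corr(perm):
            yy = _offdiag(b[np.ix_(perm, perm)])
            return np.corrcoef(x, yy)[0, 1]

        n = len(self.m1)
        r_obs = float(np.corrcoef(x, y)[0, 1])

        def extreme(r):
            if alternative == "greater":
                return r >= r_obs - 1e-12
            if alternative == "less":
                return r <= r_obs + 1e-12
            return abs(r) >= abs(r_obs) - 1e-12

        if math.factorial(n) <= EXHAUSTIVE_LIMIT:
            rs = [corr(np.asarray(p)) for p in itertools.permutations(range(n))]
            hits = sum(extreme(r) for r in rs)
            p = hits / len(rs)
            return MantelResult(
                self.trait, r_obs, r_obs**2, float(p), len(rs), "exhaustive"
            )
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if extreme(corr(rng.permutation(n))):
                hits += 1
        p = (hits + 1.0) / (n_perm + 1.0)
        return MantelResult(self.trait, r_obs, r_obs**2, float(p), n_perm, "monte-carlo")


def mantel_test(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
    trait: str = "",
) -> MantelResult:
    """Convenience wrapper: ``MantelTest(m1, m2).fit(...)``."""
    return MantelTest(m1, m2, trait=trait).fit(n_perm=n_perm, seed=seed, alternative=alternative)


def regress_matrices(m1: DistanceMatrix, m2: DistanceMatrix):
    """OLS of m2's off-diagonal pairs on m1's: (slope, intercept, r_squared).

    Descriptive only — pairs are non-independent, so test significance
    with ``mantel_test``.
    """
    if list(m1.labels) != list(m2.labels):
        raise ValueError("matrices must share identical label order")
    x, y = _offdiag(m1.values), _offdiag(m2.values)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs to regress")
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(slope), float(intercept), float(r**2)


def screen_traits(
    gm: DistanceMatrix,
    summaries: pd.DataFrame,
    traits: list[str],
    n_perm: int = 9999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mantel-screen every trait against the genetic region matrix.

    One Mantel test per trait (no multiple-testing correction by
    default, mirroring per-variable reporting); result table sorted by
    r^2 descending with a significance flag at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in traits:
        mm = morph_region_matrix(summaries, t, regions=list(gm.labels))
        res = MantelTest(gm, mm, trait=t).fit(
            n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        rows.append(
            {
                "trait": t,
                "r": res.r,
                "r_squared": res.r_squared,
                "p": res.p_value,
                "significant": bool(res.p_value <= alpha) if not res.constant else False,
                "method": res.method,
            }
        )
    cols = ["trait", "r", "r_squared", "p", "significant", "method"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("r_squared", ascending=False, ignore_index=True)
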