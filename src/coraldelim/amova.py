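"""Distance-based analysis of molecular variance (AMOVA) and pairwise Phi_ST.

The two-level AMOVA partitions squared inter-individual molecular
distances into among-group and within-group components:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within

with df_among = G-1 and df_within = N-G. The within variance component
is sigma2_b = SS_within / df_within; the among component comes from the
unbalanced-design expectation with effective group size
n' = (N - sum n_g^2 / N) / (G - 1):

    sigma2_a = (SS_among/df_among - sigma2_b) / n'
    Phi_ST   = sigma2_a / (sigma2_a + sigma2_b)

Significance is by permuting individuals among groups (group sizes
fixed), with the (b+1)/(n+1) inclusion rule. Negative variance
components are reported raw and used unclamped, flagged on the result.

Exposed statsmodels-style: ``Amova(dm, groups).fit(...)`` returns an
``AmovaResults`` with a ``summary()`` table; module-level ``amova`` is
the one-call convenience wrapper.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdist import AlignedSeqRecord, DistanceMatrix, distance_matrix

__all__ = ["Amova", "AmovaResults", "amova", "pairwise_phi_st", "clone_subset_amova"]


class DegenerateDataError(ValueError):
    pass


def _group_index(labels, groups):
    missing = [l for l in labels if l not in groups]
    if missing:
        raise KeyError(f"labels without group assignment: {missing}")
    glabels = sorted(set(groups[l] for l in labels))
    gidx = np.array([glabels.index(groups[l]) for l in labels])
    return glabels, gidx


def _ss_within(pair_d2, gi, gj, sizes):
    same = gi == gj
    per_group = np.bincount(gi[same], weights=pair_d2[same], minlength=len(sizes))
    return float((per_group / sizes).sum())


def _ss_and_phi(d2: np.ndarray, gidx: np.ndarray, n_groups: int):
    """Sums of squares and Phi_ST for one labelling. Returns tuple."""
    n = len(gidx)
    iu, ju = np.triu_indices(n, k=1)
    pair_d2 = d2[iu, ju]
    ss_total = pair_d2.sum() / n
    sizes = np.bincount(gidx, minlength=n_groups)
    ss_within = _ss_within(pair_d2, gidx[iu], gidx[ju], sizes)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0:
        raise DegenerateDataError(
            "no within-group degrees of freedom (every member its own group)"
        )
    sigma_b = ss_within / df_within
    n_eff = (n - (sizes**2).sum() / n) / df_among
    sigma_a = (ss_among / df_among - sigma_b) / n_eff
    denom = sigma_a + sigma_b
    phi = 0.0 if denom == 0 else sigma_a / denom
    return ss_total, ss_within, ss_among, sigma_a, sigma_b, phi, df_among, df_within


@dataclass
class AmovaResults:
    """Fitted AMOVA: variance partition, Phi_ST and permutation p."""

    groups: list[str]
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    negative_component: bool = False
    degenerate: bool = False
    perm_phi: np.ndarray | None = field(default=None, repr=False)

    @property
    def df_total(self) -> int:
        return self.df_among + self.df_within

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d.f.": [self.df_among, self.df_within, self.df_total],
                "S.S.": [self.ss_among, self.ss_within, self.ss_total],
                "V.C.": [self.var_among, self.var_within, self.var_among + self.var_within],
                "% variation": [self.pct_among, self.pct_within, 100.0],
            },
            index=["Among regions", "Within regions", "Total"],
        )

    def __str__(self):
        return (
            f"{self.summary()}\nPhi_ST = {self.phi_st:.4f}  "
            f"p = {self.p_value:.5f} ({self.n_permutations} permutations)"
        )


class Amova:
    """Two-level distance-based AMOVA model.

    Parameters
    ----------
    dm : DistanceMatrix
        Inter-individual molecular distances.
    groups : mapping label -> group name
        Grouping (e.g. geographic region) of every matrix label.
    """

    def __init__(self, dm: DistanceMatrix, groups: dict):
        if not np.all(np.isfinite(dm.values)):
            raise ValueError("distances must be finite")
        self.dm = dm
        self.groups = dict(groups)
        self.group_labels, self._gidx = _group_index(dm.labels, self.groups)
        if len(self.group_labels) < 2:
            raise ValueError("AMOVA needs at least two groups")

    def fit(
        self,
        n_perm: int = 10023,
        seed: int | None = None,
        permute_unit: str = "sequence",
        individuals: dict | None = None,
    ) -> AmovaResults:
        """Estimate variance components and permutation significance.

        permute_unit "sequence" shuffles individual sequences among
        groups; "individual" keeps all clones of one colony together
        (requires ``individuals`` mapping label -> colony id).
        """
        d2 = self.dm.values**2
        G = len(self.group_labels)
        if np.all(self.dm.values == 0):
            warnings.warn("all distances zero: degenerate AMOVA, Phi_ST reported 0")
            n = len(self.dm)
            return AmovaResults(
                self.group_labels, G - 1, n - G, 0.0, 0.0, 0.0, 0.0, 0.0,
                0.0, 100.0, 0.0, 1.0, 0, degenerate=True,
            )
        (ss_t, ss_w, ss_a, s_a, s_b, phi, df_a, df_w) = _ss_and_phi(d2, self._gidx, G)
        total_var = s_a + s_b
        if total_var <= 0:
            raise DegenerateDataError("non-positive total variance")
        pct_among = 100.0 * s_a / total_var
        pct_within = 100.0 * s_b / total_var

        rng = np.random.default_rng(seed)
        perm_phi = np.empty(n_perm)
        n = len(self._gidx)
        iu, ju = np.triu_indices(n, k=1)
        pair_d2 = d2[iu, ju]
        sizes = np.bincount(self._gidx, minlength=G)
        n_eff = (n - (sizes**2).sum() / n) / df_a
        ss_t_fixed = pair_d2.sum() / n

        def phi_of(gidx):
            ssw = _ss_within(pair_d2, gidx[iu], gidx[ju], sizes)
            sb = ssw / df_w
            sa = ((ss_t_fixed - ssw) / df_a - sb) / n_eff
            return 0.0 if sa + sb == 0 else sa / (sa + sb)

        if permute_unit == "sequence":
            for b in range(n_perm):
                perm_phi[b] = phi_of(self._gidx[rng.permutation(n)])
        elif permute_unit == "individual":
            if individuals is None:
                raise ValueError("individual-level permutation needs an individuals map")
            ind_of = np.asarray([individuals[l] for l in self.dm.labels])
            uniq = pd.unique(ind_of)
            ind_group = np.array(
                [self._gidx[np.where(ind_of == u)[0][0]] for u in uniq]
            )
            for b in range(n_perm):
                shuffled = ind_group[rng.permutation(len(uniq))]
                gmap = dict(zip(uniq, shuffled))
                gidx = np.array([gmap[i] for i in ind_of])
                perm_phi[b] = _ss_and_phi(d2, gidx, G)[5]
        else:
            raise ValueError(f"unknown permute_unit {permute_unit!r}")
        p = (np.sum(perm_phi >= phi) + 1.0) / (n_perm + 1.0) if n_perm else np.nan

        return AmovaResults(
            self.group_labels, df_a, df_w, ss_a, ss_w, ss_t, s_a, s_b,
            pct_among, pct_within, phi, float(p), n_perm,
            negative_component=(s_a < 0 or s_b < 0), perm_phi=perm_phi,
        )


def amova(dm: DistanceMatrix, groups: dict, n_perm: int = 10023, seed=None, **kw) -> AmovaResults:
    """Convenience wrapper: ``Amova(dm, groups).fit(n_perm, seed)``."""
    return Amova(dm, groups).fit(n_perm=n_perm, seed=seed, **kw)


def pairwise_phi_st(
    dm: DistanceMatrix, groups: dict, n_perm: int = 10023, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Phi_ST between all group pairs with permutation p-values.

    Returns (phi_st, p) as symmetric DataFrames over group labels.
    Pairs with fewer than 2 total members are skipped with a warning.
    """
    glabels, gidx = _group_index(dm.labels, groups)
    k = len(glabels)
    phi = pd.DataFrame(np.zeros((k, k)), index=glabels, columns=glabels)
    pval = pd.DataFrame(np.full((k, k), np.nan), index=glabels, columns=glabels)
    rng = np.random.default_rng(seed)
    labels = np.asarray(dm.labels)
    for a, b in itertools.combinations(range(k), 2):
        sel = np.where((gidx == a) | (gidx == b))[0]
        if len(sel) < 2:
            warnings.warn(f"pair ({glabels[a]}, {glabels[b]}): too few members, skipped")
            continue
        sub = dm.submatrix(list(labels[sel]))
        subgroups = {l: groups[l] for l in sub.labels}
        res = Amova(sub, subgroups).fit(
            n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        phi.iloc[a, b] = phi.iloc[b, a] = res.phi_st
        pval.iloc[a, b] = pval.iloc[b, a] = res.p_value
    return phi, pval


def clone_subset_amova(
    records: list[AlignedSeqRecord],
    subset_rule: str = "all",
    n_perm: int = 10023,
    seed: int | None = None,
    model: str = "k2p",
    gamma_a: float | None = 0.2,
    **model_kw,
):
    """AMOVA robustness re-analysis on subsets of the clone library.

    subset_rule:
      * ``"all"`` — every sequence (identical to a plain AMOVA);
      * ``"one_per_individual"`` — for each clone rank k, keep the k-th
        clone of every colony and run one AMOVA per rank (list returned);
      * ``"drop_group:<label>"`` — exclude one region entirely.

    Distances are recomputed on each subset; grouping is by region.
    """

    def run(recs, sd):
        dm = distance_matrix(recs, model=model, gamma_a=gamma_a, **model_kw)
        groups = {r.seq_id: r.region for r in recs}
        return Amova(dm, groups).fit(n_perm=n_perm, seed=sd)

    rng = np.random.default_rng(seed)
    if subset_rule == "all":
        return run(records, int(rng.integers(0, 2**31 - 1)))
    if subset_rule == "one_per_individual":
        by_ind: dict[str, list] = {}
        for r in records:
            by_ind.setdefault(r.individual_id, []).append(r)
        for v in by_ind.values():
            v.sort(key=lambda r: r.clone_no)
        max_clones = max(len(v) for v in by_ind.values())
        results = []
        for k in range(max_clones):
            subset = [v[min(k, len(v) - 1)] for v in by_ind.values()]
            if len({r.region for r in subset}) < 2:
                raise ValueError(f"clone subset {k} leaves fewer than two regions")
            results.append(run(subset, int(rng.integers(0, 2**31 - 1))))
        return results
    if subset_rule.startswith("drop_group:"):
        drop = subset_rule.split(":", 1)[1]
        subset = [r for r in records if r.region != drop]
        regions = {r.region for r in subset}
        if drop in {r.region for r in records} and len(regions) < 2:
            raise ValueError(f"dropping {drop!r} leaves fewer than two regions")
        if drop not in {r.region for r in records}:
            raise ValueError(f"no region named {drop!r} to drop")
        return run(subset, int(rng.integers(0, 2**31 - 1)))
    raise ValueError(f"unknown subset rule {subset_rule!r}")
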