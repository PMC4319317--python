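"""Labelled aligned sequences and molecular distances.

Sequences are cloned ribosomal ITS reads carrying colony (individual),
geographic region, species and clone-number labels. Distances between
clones use Kimura's two-parameter (K2P) model — transitions (A<->G,
C<->T) and transversions counted separately, with an optional gamma
rate-heterogeneity correction — or a weighted difference count
(transition/transversion/gap weights) of the kind fed to distance-based
AMOVA.

Sites where either sequence carries a gap or an ambiguous base are
excluded pair by pair (pairwise deletion), matching the convention of
the classic distance software for this marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignedSeqRecord",
    "SiteDifferenceCount",
    "DistanceMatrix",
    "GroupDistanceSummary",
    "AlignmentError",
    "LabellingError",
    "SaturationError",
    "read_labelled_fasta",
    "parse_label",
    "count_site_differences",
    "k2p_distance",
    "weighted_distance",
    "distance_matrix",
    "group_distance_summary",
    "slice_alignment",
]

DEFAULT_LABEL_SCHEME = ("seq_id", "region", "species", "individual", "clone")
_VALID = frozenset(b"ACGT")
_PURINES = frozenset(b"AG")


class AlignmentError(ValueError):
    """Sequences that should form one alignment have unequal lengths."""


class LabellingError(ValueError):
    """A FASTA header does not follow the declared label scheme."""


class SaturationError(ValueError):
    """K2P distance undefined: observed divergence beyond model range."""

    def __init__(self, msg: str, p: float, q: float):
        super().__init__(msg)
        self.p = p
        self.q = q


@dataclass(frozen=True)
class AlignedSeqRecord:
    """One cloned, aligned sequence with its sample labels."""

    seq_id: str
    individual_id: str
    region: str
    species: str
    clone_no: int
    bases: str

    def __post_init__(self):
        if not self.region or not self.species:
            raise LabellingError(
                f"record {self.seq_id!r}: region and species must be non-empty"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SiteDifferenceCount:
    """Pairwise site comparison tallies underlying the K2P model."""

    n_sites_compared: int
    n_transitions: int
    n_transversions: int
    n_gapped_excluded: int

    def __post_init__(self):
        if self.n_transitions + self.n_transversions > self.n_sites_compared:
            raise ValueError("more differences than compared sites")

    @property
    def p(self) -> float:
        """Proportion of transitional differences."""
        return self.n_transitions / self.n_sites_compared

    @property
    def q(self) -> float:
        """Proportion of transversional differences."""
        return self.n_transversions / self.n_sites_compared


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with model provenance."""

    labels: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimension does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], dict(self.meta))

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major pair order."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def to_phylip(self) -> str:
        lines = [f"{len(self)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + " ".join(f"{v:.8f}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        lines = [l for l in text.strip().splitlines() if l.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if all(len(r) == i for i, r in enumerate(rows)):  # lower triangle dialect
            m = np.zeros((n, n))
            for i, r in enumerate(rows):
                m[i, : len(r)] = r
            m = m + m.T
        else:
            m = np.asarray(rows)
        return cls(labels, m)


def parse_label(
    header: str,
    label_scheme: tuple[str, ...] = DEFAULT_LABEL_SCHEME,
    delimiter: str = "|",
) -> dict:
    """Split a FASTA header into sample labels per the declared scheme.

    ``individual`` may be omitted from the scheme, in which case it is
    derived from ``seq_id`` (the part before the last ``-``); ``clone``
    may likewise be derived from the trailing ``-<n>`` of the seq_id.
    """
    parts = header.strip().split(delimiter)
    if len(parts) != len(label_scheme):
        raise LabellingError(
            f"header {header!r}: expected {len(label_scheme)} "
            f"{delimiter!r}-delimited fields {label_scheme}, got {len(parts)}"
        )
    lab = dict(zip(label_scheme, (p.strip() for p in parts)))
    if "seq_id" not in lab:
        raise LabellingError(f"label scheme {label_scheme} lacks 'seq_id'")
    if "individual" not in lab:
        lab["individual"] = lab["seq_id"].rsplit("-", 1)[0]
    if "clone" not in lab:
        tail = lab["seq_id"].rsplit("-", 1)
        lab["clone"] = tail[1] if len(tail) == 2 and tail[1].isdigit() else "1"
    try:
        lab["clone"] = int(lab["clone"])
    except ValueError as e:
        raise LabellingError(f"header {header!r}: clone field not an integer") from e
    return lab


def read_labelled_fasta(
    path,
    label_scheme: tuple[str, ...] = DEFAULT_LABEL_SCHEME,
    delimiter: str = "|",
) -> list[AlignedSeqRecord]:
    """Read an aligned FASTA whose headers carry sample labels."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        lab = parse_label(rec.description, label_scheme, delimiter)
        records.append(
            AlignedSeqRecord(
                seq_id=lab["seq_id"],
                individual_id=lab["individual"],
                region=lab["region"],
                species=lab["species"],
                clone_no=lab["clone"],
                bases=str(rec.seq).upper(),
            )
        )
    if not records:
        warnings.warn(f"{path}: empty FASTA, no records parsed", stacklevel=2)
        return []
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal aligned lengths in {path}: {sorted(lengths)}")
    ids = [r.seq_id for r in records]
    if len(set(ids)) != len(ids):
        raise LabellingError("duplicate seq_id in alignment")
    return records


def slice_alignment(records: list[AlignedSeqRecord], start: int, end: int):
    """Restrict every record to alignment columns [start, end) (0-based)."""
    return [replace(r, bases=r.bases[start:end]) for r in records]


def _byte_arrays(a: AlignedSeqRecord, b: AlignedSeqRecord):
    if len(a) != len(b):
        raise AlignmentError(
            f"{a.seq_id} and {b.seq_id} have unequal lengths ({len(a)} vs {len(b)})"
        )
    return (
        np.frombuffer(a.bases.encode(), dtype=np.uint8),
        np.frombuffer(b.bases.encode(), dtype=np.uint8),
    )


_IS_VALID = np.zeros(256, dtype=bool)
for _c in _VALID:
    _IS_VALID[_c] = True
_IS_PURINE = np.zeros(256, dtype=bool)
for _c in _PURINES:
    _IS_PURINE[_c] = True
_IS_GAP = np.zeros(256, dtype=bool)
_IS_GAP[ord("-")] = True


def count_site_differences(a: AlignedSeqRecord, b: AlignedSeqRecord) -> SiteDifferenceCount:
    """Tally transitions/transversions over pairwise-complete sites.

    A site is compared only when both bases are unambiguous A/C/G/T;
    gapped or ambiguous sites are excluded for this pair (pairwise
    deletion).
    """
    xa, xb = _byte_arrays(a, b)
    ok = _IS_VALID[xa] & _IS_VALID[xb]
    n = int(ok.sum())
    if n == 0:
        raise SaturationError(
            f"{a.seq_id} vs {b.seq_id}: no comparable sites", np.nan, np.nan
        )
    diff = ok & (xa != xb)
    ts = int((diff & (_IS_PURINE[xa] == _IS_PURINE[xb])).sum())
    tv = int(diff.sum()) - ts
    return SiteDifferenceCount(n, ts, tv, len(xa) - n)


def k2p_distance(counts: SiteDifferenceCount, gamma_a: float | None = None) -> float:
    """Kimura two-parameter distance, optionally gamma-corrected.

    Without correction  d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).
    With gamma shape a  d = a/2 [(1-2P-Q)^(-1/a) - 1] + a/4 [(1-2Q)^(-1/a) - 1],
    which tends to the uncorrected form as a -> infinity.
    """
    p, q = counts.p, counts.q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined (saturated): P={p:.4f}, Q={q:.4f}", p, q
        )
    if gamma_a is None:
        return -0.5 * np.log(w1) - 0.25 * np.log(w2)
    if gamma_a <= 0:
        raise ValueError("gamma shape parameter must be positive")
    a = float(gamma_a)
    return (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (w2 ** (-1.0 / a) - 1.0)


def weighted_distance(
    a: AlignedSeqRecord,
    b: AlignedSeqRecord,
    ts_weight: float = 2.0,
    tv_weight: float = 1.0,
    gap_weight: float = 1.0,
) -> float:
    """Weighted pairwise difference count.

    ts_weight * #transitions + tv_weight * #transversions +
    gap_weight * #sites gapped in exactly one sequence. A site gapped in
    both sequences is no difference and is excluded; sites with
    ambiguity codes are excluded entirely.
    """
    if min(ts_weight, tv_weight, gap_weight) < 0:
        raise ValueError("difference weights must be non-negative")
    xa, xb = _byte_arrays(a, b)
    ok = _IS_VALID[xa] & _IS_VALID[xb]
    diff = ok & (xa != xb)
    ts = (diff & (_IS_PURINE[xa] == _IS_PURINE[xb])).sum()
    tv = diff.sum() - ts
    single_gap = _IS_GAP[xa] ^ _IS_GAP[xb]
    # only count a gap site when the non-gap partner is an unambiguous base
    single_gap &= _IS_VALID[xa] | _IS_VALID[xb]
    return float(ts_weight * ts + tv_weight * tv + gap_weight * single_gap.sum())


def distance_matrix(
    records: list[AlignedSeqRecord],
    model: str = "k2p",
    gamma_a: float | None = None,
    ts_weight: float = 2.0,
    tv_weight: float = 1.0,
    gap_weight: float = 1.0,
) -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` ("k2p" or "weighted")."""
    if len(records) < 2:
        raise ValueError("need at least two records for a distance matrix")
    n = len(records)
    m = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if model == "k2p":
                    d = k2p_distance(count_site_differences(records[i], records[j]), gamma_a)
                elif model == "weighted":
                    d = weighted_distance(
                        records[i], records[j], ts_weight, tv_weight, gap_weight
                    )
                else:
                    raise ValueError(f"unknown distance model {model!r}")
            except SaturationError:
                saturated.append((records[i].seq_id, records[j].seq_id))
                continue
            m[i, j] = m[j, i] = d
    if saturated:
        raise SaturationError(
            f"saturated pairs under {model}: {saturated}", np.nan, np.nan
        )
    meta = {"model": model, "gamma_a": gamma_a}
    if model == "weighted":
        meta.update(ts_weight=ts_weight, tv_weight=tv_weight, gap_weight=gap_weight)
    return DistanceMatrix([r.seq_id for r in records], m, meta)


@dataclass
class GroupDistanceSummary:
    """Mean pairwise distance within and between groups, with SEs."""

    groups: list[str]
    within_mean: dict
    within_se: dict
    between_mean: np.ndarray  # square over groups, diagonal = within mean
    between_se: np.ndarray

    def between(self, g1: str, g2: str) -> float:
        return float(self.between_mean[self.groups.index(g1), self.groups.index(g2)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.between_mean, index=self.groups, columns=self.groups)


def _pair_masks(labels, groups):
    garr = np.asarray([groups[l] for l in labels])
    iu, ju = np.triu_indices(len(labels), k=1)
    return garr, iu, ju


def group_distance_summary(
    dm: DistanceMatrix,
    groups: dict,
    records: list[AlignedSeqRecord] | None = None,
    n_boot: int = 500,
    seed: int | None = 0,
) -> GroupDistanceSummary:
    """Within/between-group mean distances (pair averages) and SEs.

    SEs come from a bootstrap over alignment columns (500 replicates)
    when the aligned ``records`` are supplied, otherwise from a
    bootstrap over the member pairs of each cell. A singleton group has
    no within pairs: its within mean is reported missing (NaN), never
    zero.
    """
    missing = [l for l in dm.labels if l not in groups]
    if missing:
        raise KeyError(f"labels without a group assignment: {missing}")
    glabels = sorted(set(groups[l] for l in dm.labels))
    garr, iu, ju = _pair_masks(dm.labels, groups)
    dvals = dm.values[iu, ju]

    def cell_means(values):
        k = len(glabels)
        out = np.full((k, k), np.nan)
        for a in range(k):
            for b in range(a, k):
                if a == b:
                    mask = (garr[iu] == glabels[a]) & (garr[ju] == glabels[a])
                else:
                    mask = ((garr[iu] == glabels[a]) & (garr[ju] == glabels[b])) | (
                        (garr[iu] == glabels[b]) & (garr[ju] == glabels[a])
                    )
                if mask.any():
                    out[a, b] = out[b, a] = values[mask].mean()
        return out

    means = cell_means(dvals)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(glabels), len(glabels)))
    if records is not None:
        by_id = {r.seq_id: r for r in records}
        recs = [by_id[l] for l in dm.labels]
        length = len(recs[0])
        model = dm.meta.get("model", "k2p")
        for b in range(n_boot):
            cols = rng.integers(0, length, size=length)
            resampled = [replace(r, bases="".join(r.bases[c] for c in cols)) for r in recs]
            bdm = distance_matrix(
                resampled,
                model=model,
                gamma_a=dm.meta.get("gamma_a"),
                ts_weight=dm.meta.get("ts_weight", 2.0),
                tv_weight=dm.meta.get("tv_weight", 1.0),
                gap_weight=dm.meta.get("gap_weight", 1.0),
            )
            boots[b] = cell_means(bdm.values[iu, ju])
    else:
        for b in range(n_boot):
            idx = rng.integers(0, len(dvals), size=len(dvals))
            boots[b] = cell_means(dvals[idx])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ses = np.nanstd(boots, axis=0, ddof=1)
    ses[np.isnan(means)] = np.nan

    k = len(glabels)
    within_mean = {g: float(means[i, i]) for i, g in enumerate(glabels)}
    within_se = {g: float(ses[i, i]) for i, g in enumerate(glabels)}
    return GroupDistanceSummary(glabels, within_mean, within_se, means, ses)
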