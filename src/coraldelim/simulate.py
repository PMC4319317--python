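"""Synthetic region-structured sequence and corallite-landmark data.

The sequence generator emulates a clone library of a multicopy marker
(ITS-like) sampled over geographic regions: an ancestral sequence gives
rise to per-region consensus sequences (star or serial-chain
divergence), every colony (individual) carries the regional consensus,
and each sequenced molecular clone adds its own intragenomic
substitutions. Substitutions are uniform over sites with
transition/transversion odds set by ``ts_tv_ratio``; no indels by
default (a gap-injection mode exercises pairwise deletion).

The landmark generator perturbs a template corallite — two concentric
12-point rings (outer/calice radius 0.5 mm, inner/pali radius 0.25 mm)
plus two septum-width point pairs — by a systematic per-region radial
displacement and isotropic per-corallite Gaussian noise, then applies a
random rigid motion and converts to pixels, so trait extraction must
undo nothing but the scale.

``simulate_joint`` couples the two: per-region morphological effect
sizes are set proportional to the realized genetic divergence along
the chain (mixing weight ``coupling``), so the true genetic–
morphological association is tunable from independence (0) to
deterministic proportionality (1).

Defaults mirror the study's sampling design: six regions, four
colonies per region, three clones per colony, ~700-column alignment,
ten corallites per voucher specimen.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .landmarks import LandmarkSet, TRIPLET_STATES
from .seqdist import AlignedSeqRecord

__all__ = [
    "SeqSimConfig",
    "MorphSimConfig",
    "GroundTruth",
    "simulate_sequences",
    "simulate_landmarks",
    "simulate_joint",
    "to_fasta",
    "make_template",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SeqSimConfig:
    """Study conditions for the clone-library simulator."""

    n_regions: int = 6
    individuals_per_region: int = 4
    clones_per_individual: int = 3
    alignment_length: int = 700
    ancestral_gc: float = 0.5
    between_region_subs: float = 0.0009  # expected subs/site per region branch
                                         # (calibrated to ~20% among-region variance)
    within_individual_subs: float = 0.006  # clone-level (intragenomic) subs/site
    ts_tv_ratio: float = 2.0
    outgroup_divergence: float = 0.0     # extra region at this divergence if > 0
    topology: str = "star"               # "star" or "chain" region divergence
    gap_rate: float = 0.0                # per-site gap injection per clone
    seed: int = 0
    species: str = "P. lobata"
    outgroup_species: str = "P. evermanni"

    def __post_init__(self):
        for r in (self.between_region_subs, self.within_individual_subs,
                  self.outgroup_divergence):
            if not (0 <= r < 0.5):
                raise ValueError("substitution rates must lie in [0, 0.5)")
        if min(self.n_regions, self.individuals_per_region,
               self.clones_per_individual, self.alignment_length) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def region_names(self) -> list[str]:
        return [f"Region{i+1:02d}" for i in range(self.n_regions)]


@dataclass
class MorphSimConfig:
    """Study conditions for the corallite-landmark simulator."""

    n_regions: int = 5
    specimens_per_region: int = 4
    corallites_per_specimen: int = 10
    outer_radius: float = 0.5            # calice ring, mm
    inner_radius: float = 0.25           # pali ring, mm
    septum_width: float = 0.05           # mm, the SW point pairs
    region_effects: tuple | None = None  # per-region radial displacement, mm
    corallite_noise_sd: float = 0.02     # mm, isotropic per-point
    np_means: tuple | None = None        # Poisson mean of NP per region
    nr_means: tuple | None = None
    tri_probs: tuple | None = None       # per-region (fused, trident, free)
    scale_mm_per_px: float = 0.01
    seed: int = 0
    rigid_seed: int | None = None        # rng for rigid motions only

    def __post_init__(self):
        if self.corallite_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        k = self.n_regions
        if self.region_effects is None:
            self.region_effects = tuple(0.03 * i for i in range(k))
        if self.np_means is None:
            self.np_means = tuple(5.0 + 0.5 * i for i in range(k))
        if self.nr_means is None:
            self.nr_means = tuple([5.0] * k)
        if self.tri_probs is None:
            base = [(0.7, 0.2, 0.1)] * (k - 1) + [(0.1, 0.2, 0.7)]
            self.tri_probs = tuple(base[:k])
        for p in self.tri_probs:
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("triplet-state probabilities must sum to 1")

    @property
    def region_names(self) -> list[str]:
        return [f"Region{i+1:02d}" for i in range(self.n_regions)]


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    seed: int
    region_of: dict = field(default_factory=dict)      # record/corallite id -> region
    species_of: dict = field(default_factory=dict)
    individual_of: dict = field(default_factory=dict)
    realized_region_subs: dict = field(default_factory=dict)  # region -> subs/site from ancestor
    trait_effects: dict = field(default_factory=dict)  # region -> radial effect (mm)
    coupling: float | None = None

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kw)


def _mutate(seq: np.ndarray, n_subs: int, ts_prob: float, rng) -> np.ndarray:
    """Apply ``n_subs`` point substitutions (uniform sites, K2P-like odds)."""
    out = seq.copy()
    if n_subs <= 0:
        return out
    sites = rng.integers(0, len(seq), size=n_subs)
    for s in sites:
        b = out[s]
        if rng.random() < ts_prob:
            out[s] = {0: 2, 2: 0, 1: 3, 3: 1}[int(b)]  # A<->G, C<->T
        else:
            tv = [x for x in range(4) if x != b and (x in (0, 2)) != (b in (0, 2))]
            out[s] = tv[rng.integers(0, 2)]
    return out


def _draw_subs(rate: float, length: int, rng) -> int:
    lam = rate * length
    if lam > length / 2:
        import warnings

        warnings.warn("expected substitutions exceed half the alignment: near saturation")
    return int(rng.poisson(lam))


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def simulate_sequences(cfg: SeqSimConfig):
    """Generate a region-structured clone library.

    Returns (records, ground_truth); ``to_fasta(records)`` serializes.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.alignment_length
    ts_prob = cfg.ts_tv_ratio / (cfg.ts_tv_ratio + 1.0)
    gc = cfg.ancestral_gc
    probs = np.array([(1 - gc) / 2, gc / 2, (1 - gc) / 2, gc / 2])  # A C G T
    ancestral = rng.choice(4, size=L, p=probs)

    gt = GroundTruth(seed=cfg.seed)
    records = []
    prev = ancestral
    cum_subs = 0
    for ri, region in enumerate(cfg.region_names):
        n = _draw_subs(cfg.between_region_subs, L, rng)
        if cfg.topology == "chain":
            consensus = _mutate(prev, n, ts_prob, rng)
            prev = consensus
            cum_subs += n
            gt.realized_region_subs[region] = cum_subs / L
        elif cfg.topology == "star":
            consensus = _mutate(ancestral, n, ts_prob, rng)
            gt.realized_region_subs[region] = n / L
        else:
            raise ValueError(f"unknown topology {cfg.topology!r}")
        for ii in range(cfg.individuals_per_region):
            ind = f"{region}-I{ii+1}"
            for ci in range(cfg.clones_per_individual):
                clone = _mutate(
                    consensus, _draw_subs(cfg.within_individual_subs, L, rng), ts_prob, rng
                )
                bases = _to_str(clone)
                if cfg.gap_rate > 0:
                    arr = np.frombuffer(bases.encode(), dtype=np.uint8).copy()
                    arr[rng.random(L) < cfg.gap_rate] = ord("-")
                    bases = arr.tobytes().decode()
                sid = f"{ind}-{ci+1}"
                records.append(
                    AlignedSeqRecord(sid, ind, region, cfg.species, ci + 1, bases)
                )
                gt.region_of[sid] = region
                gt.species_of[sid] = cfg.species
                gt.individual_of[sid] = ind

    if cfg.outgroup_divergence > 0:
        region = "Outgroup"
        consensus = _mutate(
            ancestral, _draw_subs(cfg.outgroup_divergence, L, rng), ts_prob, rng
        )
        gt.realized_region_subs[region] = np.nan
        for ii in range(cfg.individuals_per_region):
            ind = f"{region}-I{ii+1}"
            for ci in range(cfg.clones_per_individual):
                clone = _mutate(
                    consensus, _draw_subs(cfg.within_individual_subs, L, rng), ts_prob, rng
                )
                sid = f"{ind}-{ci+1}"
                records.append(
                    AlignedSeqRecord(
                        sid, ind, region, cfg.outgroup_species, ci + 1, _to_str(clone)
                    )
                )
                gt.region_of[sid] = region
                gt.species_of[sid] = cfg.outgroup_species
                gt.individual_of[sid] = ind
    return records, gt


def to_fasta(records: list[AlignedSeqRecord]) -> str:
    """Serialize with the pipe-delimited five-field header grammar."""
    buf = io.StringIO()
    for r in records:
        buf.write(
            f">{r.seq_id}|{r.region}|{r.species}|{r.individual_id}|{r.clone_no}\n{r.bases}\n"
        )
    return buf.getvalue()


def make_template(cfg: MorphSimConfig) -> dict:
    """The 28-point template corallite (mm, centred at the origin).

    Points 1..24 alternate outer (odd) and inner (even) rings clockwise
    from the dorsal directive; 25:26 and 27:28 are septum-width pairs.
    """
    pts = {}
    for i in range(1, 25):
        theta = -2.0 * np.pi * (i - 1) / 24.0  # clockwise
        r = cfg.outer_radius if i % 2 == 1 else cfg.inner_radius
        pts[i] = np.array([r * np.cos(theta), r * np.sin(theta)])
    mid = 0.5 * (cfg.outer_radius + cfg.inner_radius)
    for base, i in ((25, 3), (27, 15)):
        theta = -2.0 * np.pi * (i - 1) / 24.0
        radial = np.array([np.cos(theta), np.sin(theta)])
        tangent = np.array([-radial[1], radial[0]])
        centre = mid * radial
        pts[base] = centre + 0.5 * cfg.septum_width * tangent
        pts[base + 1] = centre - 0.5 * cfg.septum_width * tangent
    return pts


def _region_template(cfg: MorphSimConfig, effect: float) -> dict:
    """Template with the region's radial displacement applied."""
    scaled = MorphSimConfig(
        n_regions=cfg.n_regions,
        outer_radius=cfg.outer_radius + effect,
        inner_radius=cfg.inner_radius + 0.5 * effect,
        septum_width=cfg.septum_width,
        region_effects=cfg.region_effects,
        corallite_noise_sd=cfg.corallite_noise_sd,
        scale_mm_per_px=cfg.scale_mm_per_px,
        seed=cfg.seed,
    )
    return make_template(scaled)


def simulate_landmarks(cfg: MorphSimConfig, species_of=None):
    """Generate region-structured corallite landmark sets.

    Returns (landmark_sets, ground_truth). Noise and discrete draws
    come from ``cfg.seed``; the random rigid motion of each corallite
    comes from ``cfg.rigid_seed`` (default seed+1), so regenerating
    with a different rigid_seed but the same seed changes only the
    placement, never the traits.
    """
    rng = np.random.default_rng(cfg.seed)
    rigid = np.random.default_rng(
        cfg.rigid_seed if cfg.rigid_seed is not None else cfg.seed + 1
    )
    gt = GroundTruth(seed=cfg.seed)
    sets = []
    for ri, region in enumerate(cfg.region_names):
        effect = float(cfg.region_effects[ri])
        gt.trait_effects[region] = effect
        template = _region_template(cfg, effect)
        species = species_of[region] if species_of else "P. lobata"
        for si in range(cfg.specimens_per_region):
            spec_id = f"{region}-S{si+1}"
            for ci in range(cfg.corallites_per_specimen):
                cid = f"{spec_id}-C{ci+1}"
                theta = rigid.uniform(0, 2 * np.pi)
                rot = np.array(
                    [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                )
                shift = rigid.uniform(2.0, 8.0, size=2)
                pts = {}
                for i, p in template.items():
                    noisy = p + rng.normal(0.0, cfg.corallite_noise_sd, size=2)
                    pts[i] = tuple((rot @ noisy + shift) / cfg.scale_mm_per_px)
                tri = TRIPLET_STATES[
                    rng.choice(3, p=np.asarray(cfg.tri_probs[ri], dtype=float))
                ]
                sets.append(
                    LandmarkSet(
                        corallite_id=cid,
                        specimen_id=spec_id,
                        region=region,
                        species=species,
                        points=pts,
                        scale_mm_per_px=cfg.scale_mm_per_px,
                        n_pali=int(rng.poisson(cfg.np_means[ri])),
                        n_radi=int(rng.poisson(cfg.nr_means[ri])),
                        triplet_state=tri,
                    )
                )
                gt.region_of[cid] = region
                gt.species_of[cid] = species
                gt.individual_of[cid] = spec_id
    return sets, gt


def simulate_joint(
    seq_cfg: SeqSimConfig,
    morph_cfg: MorphSimConfig,
    coupling: float = 1.0,
    seed: int | None = None,
    effect_scale: float = 0.15,
):
    """Coupled sequence + landmark dataset with tunable concordance.

    Sequences diverge along a serial chain of regions so that realized
    inter-region genetic distance is close to a line metric; the
    per-region morphological radial effect is then

        effect_r = effect_scale * (coupling * g_r + (1 - coupling) * u_r)

    with g_r the realized cumulative genetic divergence (normalized to
    [0, 1]) and u_r iid uniform noise. coupling=1 makes inter-region
    trait distance proportional to genetic distance; coupling=0 makes
    them independent.

    Returns (records, landmark_sets, ground_truth).
    """
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    if seq_cfg.n_regions != morph_cfg.n_regions:
        raise ValueError("sequence and landmark configs must share the region set")
    seq_cfg = SeqSimConfig(**{**asdict(seq_cfg), "topology": "chain",
                              "seed": seq_cfg.seed if seed is None else seed})
    records, seq_gt = simulate_sequences(seq_cfg)

    g = np.array([seq_gt.realized_region_subs[r] for r in seq_cfg.region_names])
    g = g / g.max() if g.max() > 0 else g
    rng = np.random.default_rng((seq_cfg.seed + 7919) % 2**31)
    u = rng.uniform(0, 1, size=len(g))
    effects = effect_scale * (coupling * g + (1.0 - coupling) * u)

    mcfg = MorphSimConfig(**{**asdict(morph_cfg),
                             "n_regions": morph_cfg.n_regions,
                             "region_effects": tuple(float(e) for e in effects),
                             "seed": seq_cfg.seed + 1})
    sets, morph_gt = simulate_landmarks(mcfg)

    gt = GroundTruth(
        seed=seq_cfg.seed,
        region_of={**seq_gt.region_of, **morph_gt.region_of},
        species_of={**seq_gt.species_of, **morph_gt.species_of},
        individual_of={**seq_gt.individual_of, **morph_gt.individual_of},
        realized_region_subs=seq_gt.realized_region_subs,
        trait_effects=morph_gt.trait_effects,
        coupling=coupling,
    )
    return records, sets, gt
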