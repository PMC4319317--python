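import numpy as np
import pytest

from coraldelim.landmarks import LandmarkSet
from coraldelim.seqdist import AlignedSeqRecord
from coraldelim.simulate import MorphSimConfig, make_template


def rec(seq_id, bases, region="R1", species="P. lobata", individual=None, clone=1):
    return AlignedSeqRecord(
        seq_id=seq_id,
        individual_id=individual or seq_id.rsplit("-", 1)[0],
        region=region,
        species=species,
        clone_no=clone,
        bases=bases,
    )


@pytest.fixture
def four_seqs():
    """Four aligned sequences with hand-countable differences."""
    return [
        rec("a-1", "ACGTACGTACGTACGTACGT", region="R1"),
        rec("a-2", "ACGTACGTACGTACGTACGA", region="R1"),  # 1 tv vs a-1 (T->A)
        rec("b-1", "GCGTACGTACGTACGTACGT", region="R2"),  # 1 ts vs a-1 (A->G)
        rec("b-2", "GCGAACGTACGTACGTACGT", region="R2"),  # ts+tv vs a-1
    ]


def ring_template(outer=2.0, inner=1.0):
    """Regular 24-point double ring plus width pairs, in mm (scale 1)."""
    cfg = MorphSimConfig(n_regions=1, outer_radius=outer, inner_radius=inner)
    return {k: tuple(v) for k, v in make_template(cfg).items()}


def make_lm(points, cid="c1", spec="s1", region="R1", species="P. lobata",
            scale=1.0, n_pali=5, n_radi=5, tri="fused"):
    return LandmarkSet(
        corallite_id=cid, specimen_id=spec, region=region, species=species,
        points=points, scale_mm_per_px=scale, n_pali=n_pali, n_radi=n_radi,
        triplet_state=tri,
    )


@pytest.fixture
def ring_lm():
    return make_lm(ring_template())


def rigid_motion(points, theta, shift, rng=None):
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return {i: tuple(rot @ np.asarray(p) + shift) for i, p in points.items()}
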