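"""Synthetic fixtures: imbalanced feature tables and designed hairpins.

Two generators make every stage of the pipeline testable offline:

* :func:`gen_gaussian_bench` — a two-class numeric benchmark emulating
  the imbalanced real-vs-pseudo regime: a single positive Gaussian mode
  versus several negative modes placed at a controlled separation (in
  units of the shared unit standard deviation).  The default acceptance
  benchmark (100 positives, 5,000 negatives, 20 dimensions, separation
  2.5, 3 negative clusters) reproduces the failure mode of unweighted
  learners on imbalanced data: high SP, depressed SE.
* :func:`gen_hairpins` — stem-loop sequences whose dot-bracket structure
  is known by construction (random 5' arm + loop + reverse-complement 3'
  arm), with surrogate thermodynamic scalars so feature extraction runs
  with no folding backend.  The surrogates are marked
  ``source="synthetic"`` and are never mistaken for folding output.

Both generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .ensemble import WeightedSampleSet
from .errors import SpecError
from .features import HairpinFold, HairpinRecord

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class GaussianBenchSpec:
    n_pos: int
    n_neg: int
    dim: int
    separation: float
    neg_clusters: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 2:
            raise SpecError(f"n_pos must be >= 2, got {self.n_pos}")
        if self.n_neg < self.n_pos:
            raise SpecError(f"n_neg ({self.n_neg}) must be >= n_pos ({self.n_pos})")
        if self.dim < 2:
            raise SpecError(f"dim must be >= 2, got {self.dim}")
        if self.separation < 0:
            raise SpecError("separation must be nonnegative")
        if self.neg_clusters < 1:
            raise SpecError("neg_clusters must be >= 1")


#: Conditions used by the acceptance-grade imbalance property.
DEFAULT_BENCH = dict(n_pos=100, n_neg=5000, dim=20, separation=2.5, neg_clusters=3)


def gen_gaussian_bench(spec: GaussianBenchSpec) -> WeightedSampleSet:
    """Imbalanced two-class Gaussian benchmark (weights uninitialized).

    Positives sit at the origin with unit isotropic covariance; each
    negative cluster center lies on the sphere of radius ``separation``
    around the positive mean, so ``separation`` is the center-to-center
    distance in shared-SD units and directly controls class overlap.
    Negatives are split as evenly as possible across the clusters.  The
    cluster geometry is a fixed function of (dim, neg_clusters,
    separation): independent draws with different seeds sample the same
    population, so one spec can provide both training data and a genuine
    holdout.  Row order is positives first, then negatives by cluster.
    """
    geom = np.random.default_rng(abs(hash((spec.dim, spec.neg_clusters))) % 2**31)
    dirs = geom.standard_normal((spec.neg_clusters, spec.dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = dirs * spec.separation
    rng = np.random.default_rng(spec.seed)
    pos = rng.standard_normal((spec.n_pos, spec.dim))
    per = np.full(spec.neg_clusters, spec.n_neg // spec.neg_clusters)
    per[: spec.n_neg % spec.neg_clusters] += 1
    neg_blocks = [
        centers[c] + rng.standard_normal((int(per[c]), spec.dim))
        for c in range(spec.neg_clusters)
    ]
    X = np.vstack([pos] + neg_blocks)
    y = np.concatenate([np.ones(spec.n_pos, dtype=int),
                        np.zeros(spec.n_neg, dtype=int)])
    return WeightedSampleSet(features=X, labels=y)


@dataclass(frozen=True)
class SyntheticHairpinSpec:
    n: int
    stem_len: int
    loop_len: int
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise SpecError("n must be >= 1")
        if self.stem_len < 3:
            raise SpecError(f"stem_len must be >= 3, got {self.stem_len}")
        if self.loop_len < 3:
            raise SpecError(f"loop_len must be >= 3, got {self.loop_len}")
        if not (0.0 <= self.mutation_rate <= 0.3):
            raise SpecError("mutation_rate must lie in [0, 0.3]")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def gen_hairpins(
    spec: SyntheticHairpinSpec,
) -> List[Tuple[HairpinRecord, HairpinFold]]:
    """Designed stem-loops with analytically known folds.

    Each record is a random 5' arm, a random loop, and the exact reverse
    complement of the arm on the 3' side; per-base substitutions are then
    applied at ``mutation_rate``.  The attached structure is always the
    pre-mutation design ``(``*stem + ``.``*loop + ``)``*stem.  The
    thermodynamic scalars are simple documented surrogates — dG scales
    with the designed stem length (-1.8 kcal/mol per stacked pair), EFE
    sits slightly above it, and the remaining scalars take fixed
    plausible magnitudes — sufficient for exercising feature extraction
    offline, and flagged ``source="synthetic"``.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGU"))
    structure = "(" * spec.stem_len + "." * spec.loop_len + ")" * spec.stem_len
    out: List[Tuple[HairpinRecord, HairpinFold]] = []
    for i in range(spec.n):
        arm = "".join(rng.choice(bases, size=spec.stem_len))
        loop = "".join(rng.choice(bases, size=spec.loop_len))
        seq = list(arm + loop + reverse_complement(arm))
        if spec.mutation_rate > 0:
            hits = rng.random(len(seq)) < spec.mutation_rate
            for j in np.where(hits)[0]:
                choices = [b for b in "ACGU" if b != seq[j]]
                seq[j] = choices[rng.integers(3)]
        dg = -1.8 * (spec.stem_len - 1)
        efe = dg + 0.5
        L = len(seq)
        fold = HairpinFold(
            structure=structure,
            dG=round(dg, 2),
            EFE=round(efe, 2),
            Freq=0.8,
            Diversity=0.1 * spec.loop_len,
            dS=(0.0 if dg == 0 else (1.5 * dg - dg) * 1000.0 / 310.15),
            dH=1.5 * dg,
            Tm=65.0,
            dQ=0.2,
            dF=0.9,
            dP=spec.stem_len / L,
            dD=0.1 * spec.loop_len / L,
            source="synthetic",
        )
        out.append((HairpinRecord(id=f"synth_{i}", sequence="".join(seq)), fold))
    return out
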