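"""Disparity indices with bootstrap confidence intervals and rarefaction.

Four indices summarize a group's occupation of morphospace from its score
matrix (taxa x retained ordination axes):

- **sum of ranges** and **root-product of ranges** — the extent of
  occupied morphospace;
- **sum of variances** and **root-product of variances** — the spread of
  taxa around their own group centroid (sample variances, denominator
  m - 1).

Root-products use the k-th root (geometric mean of the per-axis values),
computed through a mean of logs; a zero range or variance on any axis
makes the corresponding root-product 0.

Uncertainty is quantified by bootstrap: groups are resampled with
replacement (at their own size, or at a common smaller size for
rarefaction) and the mean and percentile 2.5/97.5 bounds of each index
across replicates are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from morphorates.io_core import StratRange, TimeBins

logger = logging.getLogger(__name__)

INDEX_NAMES = ("sum_ranges", "rootprod_ranges", "sum_vars", "rootprod_vars")


def disparity_indices(scores: np.ndarray) -> dict[str, float]:
    """The four disparity indices of one taxon set.

    ``scores`` is an m x k matrix (m taxa, k axes).  With a single taxon
    all ranges and variances are 0.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.size == 0:
        raise ValueError("empty score set")
    m, k = scores.shape
    ranges = scores.max(axis=0) - scores.min(axis=0)
    if m >= 2:
        variances = scores.var(axis=0, ddof=1)
    else:
        variances = np.zeros(k)
    return {
        "sum_ranges": float(ranges.sum()),
        "rootprod_ranges": _root_product(ranges),
        "sum_vars": float(variances.sum()),
        "rootprod_vars": _root_product(variances),
    }


def _root_product(values: np.ndarray) -> float:
    """k-th root of the product, via mean of logs; 0 if any value is 0."""
    if np.any(values <= 0):
        return 0.0
    return float(np.exp(np.mean(np.log(values))))


@dataclass
class DisparityProfile:
    """Bootstrap summary of the four indices for one group or time bin."""

    group: str
    n: int
    mean: dict[str, float]
    ci_lo: dict[str, float]
    ci_hi: dict[str, float]
    observed: dict[str, float] = field(default_factory=dict)
    rarefied: bool = False
    rarefaction_n: "int | None" = None

    def to_records(self) -> list[dict]:
        return [
            {
                "group": self.group,
                "index": name,
                "n": self.n,
                "observed": self.observed.get(name, np.nan),
                "mean": self.mean[name],
                "ci_lo": self.ci_lo[name],
                "ci_hi": self.ci_hi[name],
                "rarefied": self.rarefied,
                "rarefaction_n": self.rarefaction_n,
            }
            for name in INDEX_NAMES
        ]


def bootstrap_disparity(
    scores: np.ndarray,
    n_reps: int = 1000,
    rarefy_to: "int | None" = None,
    seed: "int | np.random.Generator" = 0,
    group: str = "",
) -> DisparityProfile:
    """Bootstrap the disparity indices of one score set.

    Resamples with replacement ``n_reps`` times at the group's own size
    (or at ``rarefy_to`` for rarefied profiles) and summarizes each index
    by its mean and percentile 95% CI across replicates.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    m = scores.shape[0]
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    size = m if rarefy_to is None else int(rarefy_to)
    if size > m:
        raise ValueError(f"rarefy_to ({size}) exceeds group size ({m})")
    if size < 2:
        logger.warning("resample size %d < 2: variance indices degenerate", size)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    reps = np.empty((n_reps, len(INDEX_NAMES)))
    for r in range(n_reps):
        sample = scores[rng.integers(0, m, size=size)]
        vals = disparity_indices(sample)
        reps[r] = [vals[name] for name in INDEX_NAMES]
    mean = dict(zip(INDEX_NAMES, reps.mean(axis=0)))
    lo = dict(zip(INDEX_NAMES, np.percentile(reps, 2.5, axis=0)))
    hi = dict(zip(INDEX_NAMES, np.percentile(reps, 97.5, axis=0)))
    return DisparityProfile(
        group=group,
        n=m,
        mean=mean,
        ci_lo=lo,
        ci_hi=hi,
        observed=disparity_indices(scores),
        rarefied=rarefy_to is not None,
        rarefaction_n=None if rarefy_to is None else size,
    )


def bin_taxa(ranges: list[StratRange], bins: TimeBins) -> dict[str, list[str]]:
    """Assign taxa to every time bin their observed range overlaps.

    A taxon with range [lad, fad] belongs to a bin [end, start) iff
    ``fad >= end`` and ``lad < start`` (closed on the FAD side), so a
    point range falling exactly on a bin boundary lands in the younger
    bin.  Taxa overlapping no bin are logged and excluded.
    """
    membership: dict[str, list[str]] = {label: [] for label in bins.labels}
    for r in ranges:
        hit = False
        for label, start, end in bins:
            if r.fad >= end and r.lad < start:
                membership[label].append(r.taxon)
                hit = True
        if not hit:
            logger.warning(
                "taxon %r (range %.2f-%.2f Ma) overlaps no time bin; excluded",
                r.taxon, r.fad, r.lad,
            )
    return membership


def ci_significance(a: DisparityProfile, b: DisparityProfile, index: str) -> bool:
    """True when the two 95% CIs for ``index`` are disjoint."""
    if index not in INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}")
    return a.ci_hi[index] < b.ci_lo[index] or b.ci_hi[index] < a.ci_lo[index]


def group_profiles(
    scores_by_group: dict[str, np.ndarray],
    n_reps: int = 1000,
    rarefy: bool = False,
    seed: "int | np.random.Generator" = 0,
) -> list[DisparityProfile]:
    """Bootstrap profiles for several groups, optionally rarefied.

    When ``rarefy`` is True every group is resampled at the smallest
    group's size.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    rarefy_to = (
        min(np.atleast_2d(s).shape[0] for s in scores_by_group.values())
        if rarefy
        else None
    )
    return [
        bootstrap_disparity(
            scores, n_reps=n_reps, rarefy_to=rarefy_to, seed=rng, group=name
        )
        for name, scores in scores_by_group.items()
    ]


def profiles_to_frame(profiles: list[DisparityProfile]) -> pd.DataFrame:
    """Tidy table (group/bin, index, n, observed, mean, lo, hi, rarefied)."""
    return pd.DataFrame([rec for p in profiles for rec in p.to_records()])
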