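"""Representative subsampling of a pooled reference population.

When a pooled reference sample is too large for a downstream analysis, a
subsample is chosen by drawing many random subsets of candidate sizes and
scoring each against the full pool on six summary statistics: haplotype
diversity, mean pairwise Phi-st against a fixed external panel, Fu's Fs,
Tajima's D, Harpending's raggedness and theta_H. The score is the sum of
absolute standardized deviations, each statistic scaled by its delete-one
jackknife standard error in the full pool, so statistics on very different
scales contribute comparably. Undefined components (e.g. Tajima's D on a
monomorphic subset) are skipped with the remaining weights renormalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .amova import jackknife_se, phist_from_distances
from .datasets import SequenceDataset
from .errors import ValidationError
from .stats import (
    fu_fs_statistic,
    haplotype_diversity,
    harmonic_number,
    mismatch_distribution,
    raggedness,
    sequence_difference_matrix,
)

logger = logging.getLogger(__name__)

STATISTIC_NAMES = ("hd", "mean_fst", "fs", "tajima_d", "raggedness", "theta_h")


@dataclass
class SubsampleEvaluation:
    size: int
    draw_index: int
    stats_full: dict[str, float | None]
    stats_sub: dict[str, float | None]
    score: float
    indices: tuple[int, ...]


class _PoolCache:
    """Precomputed matrices for fast subset statistics on one pool + panel."""

    def __init__(self, pool: SequenceDataset, panel: SequenceDataset):
        if pool.alignment_length != panel.alignment_length:
            raise ValidationError("pool and panel must share an alignment length")
        self.n_pool = len(pool)
        combined = SequenceDataset(
            list(pool.records) + list(panel.records), pool.region_label
        )
        codes, valid = combined.to_int_matrix()
        self.codes, self.valid = codes, valid
        self.d2 = sequence_difference_matrix(codes, valid).astype(np.float64)
        self.panel_groups = [
            [self.n_pool + i for i, r in enumerate(panel.records) if r.population == p]
            for p in panel.populations
        ]
        self.hap_keys = np.unique(
            [r.sequence for r in pool.records], return_inverse=True
        )[1]

    def statistics(self, indices) -> dict[str, float | None]:
        idx = np.asarray(sorted(indices), dtype=np.int64)
        n = idx.size
        stats: dict[str, float | None] = {}
        counts = np.bincount(self.hap_keys[idx])
        counts = counts[counts > 0]
        stats["hd"] = haplotype_diversity(counts).hd
        p = counts / n
        stats["theta_h"] = 1.0 / float(np.sum(p**2)) - 1.0

        sub_d2 = self.d2[np.ix_(idx, idx)]
        iu = np.triu_indices(n, k=1)
        theta_pi = float(sub_d2[iu].mean())
        mm = mismatch_distribution(sub_d2.astype(np.int64))
        stats["raggedness"] = raggedness(mm)

        k = counts.size
        try:
            stats["fs"] = fu_fs_statistic(n, k, theta_pi)
        except Exception:
            stats["fs"] = None

        s = self._segregating_sites(idx)
        stats["tajima_d"] = self._tajima(n, s, theta_pi) if s > 0 else None

        fsts = []
        for group in self.panel_groups:
            pair_idx = np.concatenate([idx, np.asarray(group)])
            codes = np.concatenate([np.zeros(n, int), np.ones(len(group), int)])
            fsts.append(
                phist_from_distances(self.d2[np.ix_(pair_idx, pair_idx)], codes)
            )
        stats["mean_fst"] = float(np.mean(fsts))
        return stats

    def _segregating_sites(self, idx: np.ndarray) -> int:
        codes = self.codes[idx]
        valid = self.valid[idx]
        s = 0
        for j in range(codes.shape[1]):
            col = codes[valid[:, j], j]
            if col.size >= 2 and np.unique(col).size >= 2:
                s += 1
        return s

    @staticmethod
    def _tajima(n: int, s: int, theta_pi: float) -> float:
        a1 = harmonic_number(n - 1)
        a2 = harmonic_number(n - 1, power=2)
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return (theta_pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def _jackknife_scales(cache: _PoolCache) -> dict[str, float]:
    """Delete-one-individual jackknife SE of each statistic in the full pool."""
    n = cache.n_pool
    replicates: dict[str, list[float]] = {name: [] for name in STATISTIC_NAMES}
    for drop in range(n):
        idx = [i for i in range(n) if i != drop]
        stats = cache.statistics(idx)
        for name in STATISTIC_NAMES:
            if stats[name] is not None:
                replicates[name].append(stats[name])
    scales = {}
    for name, values in replicates.items():
        scales[name] = jackknife_se(values) if len(values) == n else math.nan
    return scales


def subsample_score(full: SequenceDataset, sub_indices, panel: SequenceDataset,
                    _cache: _PoolCache | None = None,
                    _scales: dict[str, float] | None = None,
                    draw_index: int = 0) -> SubsampleEvaluation:
    """Score one subsample against the full pool (lower is more similar).

    score = sum over statistics of |stat_sub - stat_full| / scale, where
    scale is the full pool's jackknife SE of that statistic; components
    undefined in either dataset, or with zero/undefined scale, are skipped
    and the total is renormalized to the full six-component scale.
    """
    sub_indices = list(sub_indices)
    if len(set(sub_indices)) != len(sub_indices):
        raise ValidationError("sub_indices must be distinct")
    if len(sub_indices) < 4:
        raise ValidationError("subsample must have at least 4 members")
    if min(sub_indices) < 0 or max(sub_indices) >= len(full):
        raise ValidationError("sub_indices out of range")
    cache = _cache if _cache is not None else _PoolCache(full, panel)
    scales = _scales if _scales is not None else _jackknife_scales(cache)
    stats_full = cache.statistics(range(len(full)))
    stats_sub = cache.statistics(sub_indices)
    total = 0.0
    used = 0
    for name in STATISTIC_NAMES:
        f, s, scale = stats_full[name], stats_sub[name], scales[name]
        if f is None or s is None or not math.isfinite(scale) or scale == 0.0:
            logger.info("subsample score: skipping undefined component %r", name)
            continue
        total += abs(s - f) / scale
        used += 1
    if used == 0:
        raise ValidationError("no defined statistic components to score")
    score = total * len(STATISTIC_NAMES) / used
    return SubsampleEvaluation(
        size=len(sub_indices), draw_index=draw_index,
        stats_full=stats_full, stats_sub=stats_sub,
        score=score, indices=tuple(sorted(sub_indices)),
    )


def select_representative_subsample(
    pool: SequenceDataset,
    panel: SequenceDataset,
    sizes=(50, 100, 150, 200),
    n_draws: int = 100,
    seed: int | None = None,
    preferred_size: int | None = None,
) -> tuple[tuple[int, ...], list[SubsampleEvaluation]]:
    """Draw random subsamples of each size, score all, return the best.

    Returns the minimum-score draw of the preferred size (default: the
    second-smallest size offered, matching the usual accuracy/cost sweet
    spot) together with the full evaluation table.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if any(s > len(pool) for s in sizes):
        raise ValidationError("subsample sizes must not exceed the pool size")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if preferred_size is None:
        preferred_size = sizes[1] if len(sizes) > 1 else sizes[0]
    if preferred_size not in sizes:
        raise ValidationError("preferred_size must be one of the offered sizes")
    rng = np.random.default_rng(seed)
    cache = _PoolCache(pool, panel)
    scales = _jackknife_scales(cache)
    evaluations: list[SubsampleEvaluation] = []
    for size in sizes:
        for draw in range(n_draws):
            if size == len(pool):
                indices = np.arange(len(pool))
            else:
                indices = rng.choice(len(pool), size=size, replace=False)
            evaluations.append(
                subsample_score(pool, indices, panel, _cache=cache,
                                _scales=scales, draw_index=draw)
            )
    best = min(
        (e for e in evaluations if e.size == preferred_size),
        key=lambda e: e.score,
    )
    return best.indices, evaluations
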