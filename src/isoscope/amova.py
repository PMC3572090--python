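"""Among-population differentiation: AMOVA / Phi-st, distance transforms,
jackknife intervals and multidimensional scaling.

The one-level analysis of molecular variance partitions the squared
molecular distances between individuals (pairwise sequence differences, or
summed absolute repeat differences for STRs) into among- and
within-population variance components; Phi-st is the among fraction.
Significance is assessed by permuting individuals among populations with
sample sizes held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.manifold import MDS as _SklearnMDS

from .errors import DegenerateGroupError
from .stats import pairwise_differences


@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    phi_st: float            # raw value (may be slightly negative)
    p_value: float
    n_permutations: int
    ssd_total: float
    ssd_among: float
    ssd_within: float

    @property
    def phi_st_display(self) -> float:
        """Phi-st clamped to >= 0 for reporting."""
        return max(self.phi_st, 0.0)


def _variance_components(d2: np.ndarray, group_codes: np.ndarray):
    """One-level AMOVA variance components from a squared-distance matrix.

    ``group_codes`` assigns each individual (row of ``d2``) to a population.
    Returns (sigma_among, sigma_within, phi_st, ssd_total, ssd_among,
    ssd_within).
    """
    n = d2.shape[0]
    groups = np.unique(group_codes)
    n_groups = groups.size
    ssd_total = float(d2.sum()) / (2.0 * n)
    ssd_within = 0.0
    sizes = np.empty(n_groups, dtype=np.float64)
    for gi, g in enumerate(groups):
        idx = np.flatnonzero(group_codes == g)
        sizes[gi] = idx.size
        ssd_within += float(d2[np.ix_(idx, idx)].sum()) / (2.0 * idx.size)
    ssd_among = ssd_total - ssd_within
    df_among = n_groups - 1
    df_within = n - n_groups
    sigma_within = ssd_within / df_within
    n_c = (n - float(np.sum(sizes**2)) / n) / df_among
    ms_among = ssd_among / df_among
    sigma_among = (ms_among - sigma_within) / n_c
    denom = sigma_among + sigma_within
    phi = sigma_among / denom if denom > 0 else 0.0
    return sigma_among, sigma_within, phi, ssd_total, ssd_among, ssd_within


def phist_from_distances(d2: np.ndarray, group_codes: np.ndarray) -> float:
    return _variance_components(d2, group_codes)[2]


def amova_phist(dataset=None, n_perm: int = 1000, seed=None, *,
                d2: np.ndarray | None = None,
                group_codes: np.ndarray | None = None) -> AmovaResult:
    """One-level AMOVA with a permutation test of Phi-st.

    Either pass a dataset (grouped by its population labels) or a
    precomputed squared-distance matrix plus integer group codes. The
    p-value is the fraction of ``n_perm`` random reassignments of
    individuals to populations (sizes fixed) with a permuted Phi-st >= the
    observed one, with the (b+1)/(m+1) correction. ``n_perm=0`` skips the
    test (p reported as NaN).
    """
    if d2 is None:
        if dataset is None:
            raise ValueError("pass either a dataset or (d2, group_codes)")
        sizes = dataset.population_sizes()
        if len(sizes) < 2:
            raise DegenerateGroupError("AMOVA requires >= 2 populations")
        for pop, size in sizes.items():
            if size < 2:
                raise DegenerateGroupError(
                    f"population {pop!r} has n={size} < 2"
                )
        pops = dataset.populations
        code_of = {p: i for i, p in enumerate(pops)}
        group_codes = np.array([code_of[r.population] for r in dataset.records])
        d2 = pairwise_differences(dataset).astype(np.float64)
    else:
        group_codes = np.asarray(group_codes)
        _, counts = np.unique(group_codes, return_counts=True)
        if counts.size < 2:
            raise DegenerateGroupError("AMOVA requires >= 2 populations")
        if (counts < 2).any():
            raise DegenerateGroupError("every population needs n >= 2")
        d2 = np.asarray(d2, dtype=np.float64)

    sig_a, sig_w, phi, ssd_t, ssd_a, ssd_w = _variance_components(d2, group_codes)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(group_codes)
            if phist_from_distances(d2, perm) >= phi:
                hits += 1
        p_value = (hits + 1.0) / (n_perm + 1.0)
    else:
        p_value = math.nan
    return AmovaResult(
        sigma_among=sig_a, sigma_within=sig_w, phi_st=phi, p_value=p_value,
        n_permutations=n_perm, ssd_total=ssd_t, ssd_among=ssd_a,
        ssd_within=ssd_w,
    )


@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray    # symmetric, zero diagonal
    p_values: np.ndarray  # symmetric, NaN diagonal


def pairwise_fst_matrix(dataset, n_perm: int = 1000, seed=None) -> FstMatrix:
    """Pairwise Phi-st between all population pairs, with permutation p's.

    Each entry is the two-population AMOVA Phi-st on the corresponding
    subset; the full distance matrix is computed once and sliced.
    """
    pops = dataset.populations
    if len(pops) < 2:
        raise DegenerateGroupError("need >= 2 populations")
    code_of = {p: i for i, p in enumerate(pops)}
    codes = np.array([code_of[r.population] for r in dataset.records])
    d2 = pairwise_differences(dataset).astype(np.float64)
    k = len(pops)
    values = np.zeros((k, k))
    p_values = np.full((k, k), np.nan)
    ss = np.random.SeedSequence(seed)
    pair_seeds = iter(ss.spawn(k * (k - 1) // 2))
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.flatnonzero((codes == i) | (codes == j))
            res = amova_phist(
                d2=d2[np.ix_(idx, idx)], group_codes=codes[idx],
                n_perm=n_perm, seed=next(pair_seeds),
            )
            values[i, j] = values[j, i] = res.phi_st
            p_values[i, j] = p_values[j, i] = res.p_value
    return FstMatrix(labels=list(pops), values=values, p_values=p_values)


def distance_transforms(fst: float) -> tuple[float, float]:
    """(Reynolds, Slatkin) linearizations of an Fst value.

    Reynolds: -ln(1 - Fst); Slatkin: Fst/(1 - Fst). Negative Fst is clamped
    to 0 before transforming; Fst = 1 maps to infinity.
    """
    f = max(float(fst), 0.0)
    if f >= 1.0:
        return math.inf, math.inf
    return -math.log(1.0 - f), f / (1.0 - f)


def jackknife_interval(dataset, statistic, unit: str = "individual"):
    """Delete-one jackknife (min, max) interval of a dataset statistic.

    ``statistic`` is a callable mapping a dataset to a real number.
    ``unit='individual'`` deletes one record at a time (populations with
    only 2 members are protected from deletion so grouped statistics stay
    defined); ``unit='population'`` deletes whole populations (requires
    >= 3 populations so every replicate still has >= 2 groups).
    """
    values = jackknife_replicates(dataset, statistic, unit=unit)
    return float(min(values)), float(max(values))


def jackknife_replicates(dataset, statistic, unit: str = "individual"):
    n = len(dataset)
    values = []
    if unit == "individual":
        sizes = dataset.population_sizes()
        if min(sizes.values()) < 3:
            protected = {p for p, s in sizes.items() if s <= 2}
        else:
            protected = set()
        deletable = [
            i for i, r in enumerate(dataset.records) if r.population not in protected
        ]
        if len(deletable) < 2:
            raise DegenerateGroupError("too few deletable records for a jackknife")
        for drop in deletable:
            sub = dataset.subset([i for i in range(n) if i != drop])
            values.append(statistic(sub))
    elif unit == "population":
        pops = dataset.populations
        if len(pops) < 3:
            raise DegenerateGroupError(
                "population-level jackknife requires >= 3 populations"
            )
        for drop in pops:
            sub = dataset.restrict_to([p for p in pops if p != drop])
            values.append(statistic(sub))
    else:
        raise ValueError(f"unknown jackknife unit {unit!r}")
    return values


def jackknife_se(values) -> float:
    """Jackknife standard error from delete-one replicate values."""
    v = np.asarray(values, dtype=np.float64)
    m = v.size
    return math.sqrt((m - 1.0) / m * float(np.sum((v - v.mean()) ** 2)))


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) scaling start configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def mds_embed(distances, dims: int = 2, seed: int = 0):
    """Nonmetric MDS of a distance matrix; returns (coordinates, stress-1).

    Accepts an :class:`FstMatrix` or a plain symmetric non-negative array.
    The embedding is SMACOF with monotone regression started from the
    classical-scaling configuration, so a fixed input yields a fixed
    layout. Stress-1 = sqrt(sum (dhat - d*)^2 / sum dhat^2).
    """
    if isinstance(distances, FstMatrix):
        d = np.asarray(distances.values, dtype=np.float64)
    else:
        d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    d = np.clip(d, 0.0, None)
    if np.allclose(d, 0.0):
        return np.zeros((d.shape[0], dims)), 0.0
    kwargs = dict(
        n_components=dims,
        n_init=1,
        max_iter=1000,
        eps=1e-12,
        normalized_stress=True,
        random_state=seed,
    )
    try:  # scikit-learn >= 1.9 API
        mds = _SklearnMDS(metric="precomputed", metric_mds=False,
                          init="classical_mds", **kwargs)
        coords = mds.fit_transform(d)
    except TypeError:  # older scikit-learn
        mds = _SklearnMDS(metric=False, dissimilarity="precomputed", **kwargs)
        coords = mds.fit_transform(d, init=_classical_scaling(d, dims))
    return coords, float(mds.stress_)
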