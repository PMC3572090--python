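"""Within-population diversity and neutrality statistics.

Implements the classical mtDNA / Y-STR summary statistics used to screen
small populations for isolation signatures:

* haplotype collapsing and Nei's haplotype diversity (HD) with its
  sampling standard error,
* pairwise sequence / repeat-count differences with pairwise deletion of
  gap and ambiguous sites,
* the mismatch distribution and Harpending's raggedness index,
* Tajima's D,
* Fu's Fs via the Ewens sampling formula (exact log-domain Stirling-number
  recursion) with a coalescent-simulation p-value,
* the theta estimators theta_pi (mean pairwise differences), theta_S
  (Watterson) and theta_H (homozygosity inversion under infinite alleles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .datasets import MISSING_REPEAT, SequenceDataset, StrDataset
from .errors import UndefinedStatisticError, ValidationError

# ---------------------------------------------------------------------------
# Haplotype collapsing


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with a populations x haplotypes count matrix."""

    haplotypes: list
    populations: list[str]
    counts: np.ndarray  # (n_pops, n_haplotypes) non-negative ints

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def population_counts(self, population: str) -> np.ndarray:
        return self.counts[self.populations.index(population)]


def collapse_haplotypes(dataset) -> HaplotypeTable:
    """Collapse records into distinct haplotypes, counted per population.

    Sequences are compared on the full aligned string; 'N' and '-' are
    literal characters, so an ambiguous base never merges two otherwise
    distinct haplotypes (conservative: reproducible haplotype counts).
    STR profiles are compared as exact repeat-count tuples.
    """
    if isinstance(dataset, SequenceDataset):
        keys = [r.sequence for r in dataset.records]
    elif isinstance(dataset, StrDataset):
        keys = [r.repeats for r in dataset.records]
    else:
        raise TypeError(f"unsupported dataset type {type(dataset)!r}")
    populations = dataset.populations
    pop_index = {p: i for i, p in enumerate(populations)}
    hap_index: dict = {}
    haplotypes: list = []
    cells: list[tuple[int, int]] = []
    for r, key in zip(dataset.records, keys):
        j = hap_index.get(key)
        if j is None:
            j = len(haplotypes)
            hap_index[key] = j
            haplotypes.append(key)
        cells.append((pop_index[r.population], j))
    counts = np.zeros((len(populations), len(haplotypes)), dtype=np.int64)
    for i, j in cells:
        counts[i, j] += 1
    return HaplotypeTable(haplotypes, populations, counts)


# ---------------------------------------------------------------------------
# Haplotype diversity (Nei 1987)


@dataclass
class DiversityResult:
    hd: float
    hd_sd: float
    k: int
    n: int


def haplotype_diversity(counts) -> DiversityResult:
    """Nei's haplotype diversity HD = n/(n-1) (1 - sum p_i^2) with its SE.

    ``counts`` is a vector of haplotype counts for one population. The
    standard error follows Nei's sampling-variance formula

        V(HD) = 2/(n(n-1)) * { 2(n-2) [sum p^3 - (sum p^2)^2]
                               + sum p^2 - (sum p^2)^2 }.
    """
    counts = np.asarray(counts, dtype=np.float64)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity requires n >= 2")
    p = counts / n
    sum_p2 = float(np.sum(p**2))
    sum_p3 = float(np.sum(p**3))
    hd = n / (n - 1.0) * (1.0 - sum_p2)
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2)
    )
    return DiversityResult(hd=float(hd), hd_sd=math.sqrt(max(var, 0.0)),
                           k=int(len(counts)), n=int(n))


# ---------------------------------------------------------------------------
# Pairwise differences


def sequence_difference_matrix(codes: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Pairwise differing-site counts with pairwise deletion of '-'/'N'."""
    n = codes.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both_valid = valid & valid[i]
        out[i] = ((codes != codes[i]) & both_valid).sum(axis=1)
    np.fill_diagonal(out, 0)
    return out


def str_difference_matrix(repeats: np.ndarray) -> np.ndarray:
    """Sum over loci of absolute repeat differences."""
    diff = np.abs(repeats[:, None, :] - repeats[None, :, :]).sum(axis=2)
    return diff.astype(np.int64)


def pairwise_differences(dataset) -> np.ndarray:
    """Pairwise distance matrix for a dataset (see module docstring).

    For sequences: number of differing sites, sites with '-' or 'N' in
    either sequence excluded pairwise. For STR profiles: sum of absolute
    repeat differences over loci (records with missing calls must be
    removed first via :meth:`StrDataset.complete`).
    """
    if isinstance(dataset, SequenceDataset):
        if len(dataset) < 2:
            raise UndefinedStatisticError("pairwise differences require >= 2 records")
        codes, valid = dataset.to_int_matrix()
        return sequence_difference_matrix(codes, valid)
    if isinstance(dataset, StrDataset):
        if len(dataset) < 2:
            raise UndefinedStatisticError("pairwise differences require >= 2 records")
        if dataset.has_missing():
            raise ValidationError(
                "StrDataset contains missing repeat counts; call .complete() first"
            )
        return str_difference_matrix(dataset.to_matrix())
    raise TypeError(f"unsupported dataset type {type(dataset)!r}")


# ---------------------------------------------------------------------------
# Mismatch distribution and raggedness


@dataclass
class MismatchDistribution:
    classes: np.ndarray  # counts of pairs at 0..d_max differences
    n_pairs: int

    def frequencies(self) -> np.ndarray:
        return self.classes / self.n_pairs


def mismatch_distribution(diff_matrix: np.ndarray) -> MismatchDistribution:
    n = diff_matrix.shape[0]
    if n < 2:
        raise UndefinedStatisticError("mismatch distribution requires n >= 2")
    iu = np.triu_indices(n, k=1)
    diffs = diff_matrix[iu]
    d_max = int(diffs.max())
    classes = np.bincount(diffs, minlength=d_max + 1)
    return MismatchDistribution(classes=classes, n_pairs=len(diffs))


def raggedness(mismatch: MismatchDistribution) -> float:
    """Harpending's raggedness r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2.

    x are the relative frequencies of the mismatch classes 0..d and
    x_{d+1} = 0; small values indicate the smooth unimodal distribution
    expected after demographic expansion.
    """
    x = np.append(mismatch.frequencies(), 0.0)
    return float(np.sum(np.diff(x) ** 2))


def mismatch_and_raggedness(dataset_or_matrix) -> tuple[MismatchDistribution, float]:
    if isinstance(dataset_or_matrix, np.ndarray):
        diff = dataset_or_matrix
    else:
        diff = pairwise_differences(dataset_or_matrix)
    mm = mismatch_distribution(diff)
    return mm, raggedness(mm)


# ---------------------------------------------------------------------------
# Segregating sites and theta estimators


def segregating_sites(dataset: SequenceDataset) -> int:
    """Number of sites with >= 2 distinct called bases (A/C/G/T)."""
    codes, valid = dataset.to_int_matrix()
    s = 0
    for j in range(codes.shape[1]):
        col = codes[valid[:, j], j]
        if col.size >= 2 and np.unique(col).size >= 2:
            s += 1
    return s


def harmonic_number(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n + 1)))


def theta_estimators(dataset) -> tuple[float, float, float]:
    """(theta_pi, theta_S, theta_H) for one population sample.

    theta_pi: mean pairwise differences; theta_S: Watterson's S/a1 (0 for
    STR input, where the infinite-sites S is undefined); theta_H: inversion
    of expected homozygosity under the infinite-alleles model,
    F = 1/(1+theta) with F = sum p_i^2 over haplotype frequencies.
    """
    n = len(dataset)
    if n < 2:
        raise UndefinedStatisticError("theta estimators require n >= 2")
    diff = pairwise_differences(dataset)
    iu = np.triu_indices(n, k=1)
    theta_pi = float(diff[iu].mean())
    if isinstance(dataset, SequenceDataset):
        s = segregating_sites(dataset)
        theta_s = s / harmonic_number(n - 1)
    else:
        theta_s = 0.0
    table = collapse_haplotypes(dataset)
    p = table.counts.sum(axis=0) / table.total
    f_hat = float(np.sum(p**2))
    theta_h = 1.0 / f_hat - 1.0
    return theta_pi, theta_s, theta_h


# ---------------------------------------------------------------------------
# Tajima's D


def tajimas_d(dataset: SequenceDataset) -> float:
    """Tajima's D with the standard 1989 constants.

    Raises :class:`UndefinedStatisticError` when there are no segregating
    sites (the statistic is undefined, not zero).
    """
    n = len(dataset)
    if n < 2:
        raise UndefinedStatisticError("Tajima's D requires n >= 2")
    s = segregating_sites(dataset)
    if s == 0:
        raise UndefinedStatisticError("Tajima's D undefined for monomorphic samples")
    diff = pairwise_differences(dataset)
    iu = np.triu_indices(n, k=1)
    theta_pi = float(diff[iu].mean())
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return (theta_pi - s / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling formula


@lru_cache(maxsize=64)
def _log_stirling_first_row(n: int) -> tuple[float, ...]:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Exact log-domain recursion |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)|.
    """
    row = np.full(n + 1, -np.inf)
    row[min(1, n)] = 0.0  # |s(1,1)| = 1 (and |s(0,0)| = 1)
    if n == 0:
        row[0] = 0.0
        return tuple(row)
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 2] = np.logaddexp(
            math.log(m) + row[1 : m + 2], row[0 : m + 1]
        )
        row = new
    return tuple(row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling formula.

    P(K=k) = |s(n,k)| theta^k / (theta (theta+1) ... (theta+n-1)).
    """
    if theta <= 0:
        raise ValidationError("Ewens pmf requires theta > 0")
    log_s = np.array(_log_stirling_first_row(n))
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    k = np.arange(n + 1)
    return log_s + k * math.log(theta) - log_rising


def fu_fs_statistic(n: int, k_obs: int, theta_pi: float) -> float:
    """Fu's Fs = ln(S' / (1 - S')) with S' = P(K >= k_obs | theta = theta_pi)."""
    if k_obs < 2 or theta_pi <= 0:
        raise UndefinedStatisticError("Fu's Fs requires k >= 2 and theta_pi > 0")
    log_pmf = ewens_log_pmf(n, theta_pi)
    log_s_prime = float(logsumexp(log_pmf[k_obs:]))
    log_one_minus = float(logsumexp(log_pmf[:k_obs]))
    return log_s_prime - log_one_minus


def _simulate_neutral_fs(n: int, theta: float, rng: np.random.Generator) -> float:
    """Fs for one neutral constant-size coalescent sample at scaled theta.

    Kingman genealogy of n tips; infinite-sites mutations dropped on
    branches at rate theta/2 per lineage per coalescent time unit. Returns
    Fs computed from the simulated sample's own k and mean pairwise
    differences (undefined draws return +inf, i.e. never more negative
    than any observed value).
    """
    # Simulate coalescent intervals and record, per tip, the set of mutations.
    lineages = [frozenset([i]) for i in range(n)]
    mutations_of_tip: list[set[int]] = [set() for _ in range(n)]
    next_mut = 0
    k = n
    while k > 1:
        rate_coal = k * (k - 1) / 2.0
        t = rng.exponential(1.0 / rate_coal)
        # mutations on each of the k lineages during t
        for lin in lineages:
            n_mut = rng.poisson(theta / 2.0 * t)
            for _ in range(n_mut):
                for tip in lin:
                    mutations_of_tip[tip].add(next_mut)
                next_mut += 1
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = lineages[i] | lineages[j]
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        k -= 1
    haplotypes = [frozenset(m) for m in mutations_of_tip]
    k_sim = len(set(haplotypes))
    total = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += len(mutations_of_tip[i] ^ mutations_of_tip[j])
            n_pairs += 1
    theta_pi_sim = total / n_pairs
    if k_sim < 2 or theta_pi_sim <= 0:
        return math.inf
    return fu_fs_statistic(n, k_sim, theta_pi_sim)


def fu_fs(dataset, p_reps: int = 1000, seed=None) -> tuple[float, float]:
    """Fu's Fs and its simulation p-value for one population sample.

    The p-value is the fraction of ``p_reps`` neutral coalescent samples
    (at theta equal to the observed mean pairwise differences) whose Fs is
    <= the observed Fs; strongly negative Fs (an excess of haplotypes)
    signals demographic expansion.
    """
    n = len(dataset)
    table = collapse_haplotypes(dataset)
    k_obs = table.n_haplotypes
    theta_pi, _, _ = theta_estimators(dataset)
    fs_obs = fu_fs_statistic(n, k_obs, theta_pi)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(p_reps):
        if _simulate_neutral_fs(n, theta_pi, rng) <= fs_obs:
            hits += 1
    return fs_obs, hits / p_reps


# ---------------------------------------------------------------------------
# Per-population summary (the Table-1-style report)


@dataclass
class NeutralityResult:
    fs: float | None
    fs_p: float | None
    tajima_d: float | None
    raggedness_r: float
    theta_pi: float
    theta_s: float
    theta_h: float


def population_summary(dataset, population: str, p_reps: int = 1000, seed=None):
    """(DiversityResult, NeutralityResult) for one population of a dataset."""
    sub = dataset.restrict_to([population])
    table = collapse_haplotypes(sub)
    div = haplotype_diversity(table.counts.sum(axis=0))
    theta_pi, theta_s, theta_h = theta_estimators(sub)
    _, r = mismatch_and_raggedness(sub)
    try:
        fs, fs_p = fu_fs(sub, p_reps=p_reps, seed=seed)
    except UndefinedStatisticError:
        fs, fs_p = None, None
    tajima: float | None
    try:
        tajima = tajimas_d(sub) if isinstance(sub, SequenceDataset) else None
    except UndefinedStatisticError:
        tajima = None
    neut = NeutralityResult(
        fs=fs, fs_p=fs_p, tajima_d=tajima, raggedness_r=r,
        theta_pi=theta_pi, theta_s=theta_s, theta_h=theta_h,
    )
    return div, neut
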