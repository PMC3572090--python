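"""Structured-coalescent simulator with growth, migration and splits.

Simulates genealogies backward in time for a "source + sinks" demography:
small founded populations (sinks) that split from a large ancestral
population (source), each with forward-time exponential growth (so sizes
shrink toward the past), per-generation backward migration, and population
splits at which all lineages of a child deme move into its parent.

Time is measured in generations before sampling. A deme with sampling-time
size ``ne0`` and growth rate ``g`` has Ne(t) = max(ne0 * exp(-g t), 1)
looking backward; the unit floor guarantees a most recent common ancestor.
Waiting times under the time-inhomogeneous coalescence rate
C(k,2) / Ne(t) are drawn by exact inverse-CDF time rescaling (no thinning);
migration clocks are homogeneous exponentials. Effective sizes are haploid
(uniparental markers), with no diploid scaling.

Two mutation layers turn a genealogy into data: an HKY substitution process
for mtDNA sequence (exact per-branch transition probabilities from the
eigendecomposition of the rate matrix) and a symmetric single-step
stepwise model for Y-STR repeat counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import (
    DEFAULT_GENERATION_YEARS,
    DEFAULT_HKY_FREQS,
    DEFAULT_HKY_KAPPA,
    DEFAULT_MT_RATE_PER_YEAR,
    DEFAULT_STR_RATES,
    ScenarioSpec,
)
from .datasets import SequenceDataset, SequenceRecord, StrDataset, StrRecord
from .errors import ValidationError

# ---------------------------------------------------------------------------
# Demography


@dataclass(frozen=True)
class PopulationConfig:
    name: str
    ne_at_sampling: float
    growth_rate: float = 0.0  # forward per-generation exponential rate
    #: Backward time beyond which the size stays constant at Ne(horizon).
    growth_horizon: float = math.inf

    def size_at(self, t: float) -> float:
        t_eff = min(t, self.growth_horizon)
        return max(self.ne_at_sampling * math.exp(-self.growth_rate * t_eff), 1.0)


@dataclass
class DemographyModel:
    """Populations, backward migration matrix and split events.

    ``migration[i][j]`` is the per-generation probability that a lineage
    currently in deme i traces its ancestry to deme j (backward semantics,
    as in coalescent samplers). ``splits`` are (child, parent, time)
    triples; at a split time every lineage in the child moves to the
    parent and the child deme closes. The split graph must be a tree rooted
    at a single source deme.
    """

    populations: list[PopulationConfig]
    migration: np.ndarray
    splits: list[tuple[str, str, float]] = field(default_factory=list)
    generation_years: float = DEFAULT_GENERATION_YEARS

    def __post_init__(self) -> None:
        self.migration = np.asarray(self.migration, dtype=np.float64)
        n = len(self.populations)
        if self.migration.shape != (n, n):
            raise ValidationError("migration matrix shape must match population count")
        off = self.migration[~np.eye(n, dtype=bool)]
        if ((off < 0) | (off >= 1)).any():
            raise ValidationError("migration entries must lie in [0, 1)")
        names = [p.name for p in self.populations]
        if len(set(names)) != n:
            raise ValidationError("population names must be unique")
        children = [c for c, _, _ in self.splits]
        if len(set(children)) != len(children):
            raise ValidationError("each child deme may split exactly once")
        for child, parent, t in self.splits:
            if child not in names or parent not in names:
                raise ValidationError(f"unknown deme in split {child!r} -> {parent!r}")
            if t <= 0:
                raise ValidationError("split times must be strictly positive")
        roots = set(names) - set(children)
        if not roots:
            raise ValidationError("split graph must leave at least one root deme")
        # reject cycles: walk each deme to the root
        parent_of = {c: p for c, p, _ in self.splits}
        for name in names:
            seen = set()
            cur = name
            while cur in parent_of:
                if cur in seen:
                    raise ValidationError("split graph contains a cycle")
                seen.add(cur)
                cur = parent_of[cur]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def root(self) -> str:
        """The unique final deme (errors for multi-root island models)."""
        children = {c for c, _, _ in self.splits}
        roots = [n for n in self.names if n not in children]
        if len(roots) != 1:
            raise ValidationError(f"no unique root deme: {roots}")
        return roots[0]


# ---------------------------------------------------------------------------
# Genealogy


@dataclass
class Genealogy:
    """Binary coalescent tree: tips 0..n-1 at time 0, internal nodes after.

    ``node_time`` is in generations before sampling; ``node_parent`` is -1
    for the root; ``tip_populations`` records the sampling deme per tip.
    """

    node_time: np.ndarray
    node_parent: np.ndarray
    tip_populations: list[str]

    @property
    def n_tips(self) -> int:
        return len(self.tip_populations)

    @property
    def n_nodes(self) -> int:
        return len(self.node_time)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.node_parent < 0)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (generations)."""
        lengths = np.zeros(self.n_nodes)
        has_parent = self.node_parent >= 0
        lengths[has_parent] = (
            self.node_time[self.node_parent[has_parent]] - self.node_time[has_parent]
        )
        return lengths

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def preorder(self) -> list[int]:
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.node_parent[v]
            if p >= 0:
                children[p].append(v)
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(children[v])
        return order


# ---------------------------------------------------------------------------
# Waiting-time draws


def _coalescence_waiting_time(pop: PopulationConfig, k: int, t0: float,
                              target: float) -> float:
    """Time until cumulative coalescence hazard from t0 reaches ``target``.

    Hazard is C(k,2)/Ne(t) with Ne(t) piecewise: exponential decay toward
    the past until the unit floor (or the growth horizon), constant after.
    Returns math.inf only for backward-growing demes whose total hazard is
    finite (g < 0 without floor relevance never occurs here because sizes
    are floored at 1, keeping the hazard bounded below).
    """
    c = k * (k - 1) / 2.0
    if c <= 0 or target <= 0:
        return math.inf
    g = pop.growth_rate
    ne0 = pop.ne_at_sampling
    if g == 0.0:
        return target * max(ne0, 1.0) / c

    # Boundary where decay stops: floor at size 1, or the growth horizon.
    if g > 0:
        t_stop = math.log(ne0) / g if ne0 > 1.0 else 0.0
        t_stop = min(t_stop, pop.growth_horizon)
    else:
        t_stop = pop.growth_horizon  # size grows backward until horizon
    const_size = pop.size_at(t_stop)

    remaining = target
    t_orig = t0
    if t0 < t_stop:
        if math.isinf(t_stop):
            # g < 0 with no horizon: total hazard is finite
            limit = -c * math.exp(g * t0) / (ne0 * g)
            if remaining >= limit:
                return math.inf
            return math.log(math.exp(g * t0) + remaining * ne0 * g / c) / g - t0
        # hazard integral over the exponential-decay piece
        full = c / (ne0 * g) * (math.exp(g * t_stop) - math.exp(g * t0))
        if remaining <= full:
            return math.log(math.exp(g * t0) + remaining * ne0 * g / c) / g - t0
        remaining -= full
        t0 = t_stop
    # constant piece
    return (t0 - t_orig) + remaining * const_size / c


def simulate_genealogy(model: DemographyModel, sample_sizes: dict[str, int],
                       rng: np.random.Generator) -> Genealogy:
    """Run the structured-coalescent event loop to the MRCA.

    ``sample_sizes`` maps deme name to the number of tips sampled there at
    time 0. Competing clocks per active deme: one inhomogeneous coalescence
    clock and one homogeneous migration clock per destination; at each
    split time the child deme's lineages move to the parent.
    """
    names = model.names
    n_demes = len(names)
    total_tips = sum(sample_sizes.get(name, 0) for name in names)
    if total_tips < 1:
        raise ValidationError("at least one lineage must be sampled")

    tip_populations: list[str] = []
    lineages: list[list[int]] = [[] for _ in range(n_demes)]
    node = 0
    for d, name in enumerate(names):
        for _ in range(sample_sizes.get(name, 0)):
            lineages[d].append(node)
            tip_populations.append(name)
            node += 1

    n_nodes_final = 2 * total_tips - 1
    node_time = np.zeros(n_nodes_final)
    node_parent = np.full(n_nodes_final, -1, dtype=np.int64)

    splits = sorted(model.splits, key=lambda s: s[2])
    split_idx = 0
    mig = model.migration
    closed = np.zeros(n_demes, dtype=bool)

    t = 0.0
    active = total_tips
    guard = 0
    while active > 1:
        guard += 1
        if guard > 100 * n_nodes_final + 1000:
            raise RuntimeError("structured coalescent failed to terminate")
        next_split_t = splits[split_idx][2] if split_idx < len(splits) else math.inf

        best_time = math.inf
        best_event = None  # ("coal", d) | ("mig", d, dest)
        for d in range(n_demes):
            k = len(lineages[d])
            if k == 0 or closed[d]:
                continue
            if k >= 2:
                wait = _coalescence_waiting_time(
                    model.populations[d], k, t, rng.exponential(1.0)
                )
                if t + wait < best_time:
                    best_time = t + wait
                    best_event = ("coal", d)
            open_dest = [e for e in range(n_demes) if e != d and not closed[e]]
            rates = np.array([mig[d, e] for e in open_dest])
            total_rate = k * float(rates.sum())
            if total_rate > 0:
                wait = rng.exponential(1.0 / total_rate)
                if t + wait < best_time:
                    dest = open_dest[
                        int(rng.choice(len(open_dest), p=rates / rates.sum()))
                    ]
                    best_time = t + wait
                    best_event = ("mig", d, dest)

        if best_time >= next_split_t:
            if math.isinf(next_split_t):
                raise ValidationError(
                    "lineages are stranded in disconnected demes with no "
                    "migration and no future split"
                )
            child, parent, t_split = splits[split_idx]
            ci, pi = model.index(child), model.index(parent)
            lineages[pi].extend(lineages[ci])
            lineages[ci] = []
            closed[ci] = True
            t = t_split
            split_idx += 1
            continue

        t = best_time
        if best_event[0] == "coal":
            d = best_event[1]
            k = len(lineages[d])
            i, j = rng.choice(k, size=2, replace=False)
            a = lineages[d][int(i)]
            b = lineages[d][int(j)]
            new = node
            node += 1
            node_time[new] = t
            node_parent[a] = new
            node_parent[b] = new
            lineages[d] = [x for x in lineages[d] if x not in (a, b)]
            lineages[d].append(new)
            active -= 1
        else:
            _, d, dest = best_event
            k = len(lineages[d])
            i = int(rng.integers(k))
            lineages[dest].append(lineages[d].pop(i))

    return Genealogy(
        node_time=node_time[:node],
        node_parent=node_parent[:node],
        tip_populations=tip_populations,
    )


# ---------------------------------------------------------------------------
# Mutation models


@dataclass(frozen=True)
class HkyParams:
    region_rate_per_year: float = DEFAULT_MT_RATE_PER_YEAR
    kappa: float = DEFAULT_HKY_KAPPA
    base_frequencies: tuple[float, float, float, float] = DEFAULT_HKY_FREQS
    length_bp: int = 333

    def __post_init__(self) -> None:
        if self.region_rate_per_year < 0 or self.kappa < 0:
            raise ValidationError("rates must be >= 0")
        if self.length_bp < 1:
            raise ValidationError("length_bp must be >= 1")
        if not math.isclose(sum(self.base_frequencies), 1.0, abs_tol=1e-8):
            raise ValidationError("base frequencies must sum to 1")


@dataclass(frozen=True)
class SmmParams:
    locus_names: tuple[str, ...] = tuple(DEFAULT_STR_RATES)
    rates_per_generation: tuple[float, ...] = tuple(DEFAULT_STR_RATES.values())
    root_allele: int = 15

    def __post_init__(self) -> None:
        if len(self.locus_names) != len(self.rates_per_generation):
            raise ValidationError("one rate per locus required")
        if any(r < 0 for r in self.rates_per_generation):
            raise ValidationError("rates must be >= 0")
        if self.root_allele < 1:
            raise ValidationError("root allele must be >= 1")


@dataclass(frozen=True)
class MutationSpec:
    """Mutation layer choice: HKY sequence model or stepwise STR model."""

    model: str  # "hky" | "smm"
    hky: HkyParams | None = None
    smm: SmmParams | None = None

    def __post_init__(self) -> None:
        if self.model == "hky":
            if self.hky is None:
                object.__setattr__(self, "hky", HkyParams())
        elif self.model == "smm":
            if self.smm is None:
                object.__setattr__(self, "smm", SmmParams())
        else:
            raise ValidationError(f"unknown mutation model {self.model!r}")


_TRANSITION_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T


def hky_rate_matrix(kappa: float, freqs) -> np.ndarray:
    """HKY rate matrix scaled to one expected substitution per site per unit."""
    pi = np.asarray(freqs, dtype=np.float64)
    q = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            q[a, b] = pi[b] * (kappa if _TRANSITION_PARTNER[a] == b else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(np.sum(pi * np.diag(q)))
    return q / mean_rate


def _hky_transition_probs(q: np.ndarray, pi: np.ndarray,
                          times: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for many t at once, via the symmetrized eigensystem."""
    sqrt_pi = np.sqrt(pi)
    sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
    evals, evecs = np.linalg.eigh((sym + sym.T) / 2.0)
    left = evecs / sqrt_pi[:, None]
    right = evecs.T * sqrt_pi[None, :]
    expd = np.exp(np.multiply.outer(times, evals))  # (m, 4)
    p = np.einsum("ak,mk,kb->mab", left, expd, right)
    return np.clip(p, 0.0, None)


def apply_hky_mutations(tree: Genealogy, spec: MutationSpec,
                        rng: np.random.Generator,
                        generation_years: float = DEFAULT_GENERATION_YEARS,
                        region_label: str = "simulated",
                        sample_prefix: str = "sim") -> SequenceDataset:
    """Evolve sequences down the genealogy under the HKY model.

    The per-site, per-generation rate is the whole-region yearly rate times
    the generation time divided by the region length; the root sequence is
    drawn from the stationary base frequencies and each branch applies the
    exact finite-time HKY transition matrix site by site.
    """
    if spec.model != "hky":
        raise ValidationError("apply_hky_mutations needs an HKY MutationSpec")
    params = spec.hky
    length = params.length_bp
    pi = np.asarray(params.base_frequencies)
    mu_site_per_gen = (
        params.region_rate_per_year * generation_years / length
    )
    q = hky_rate_matrix(params.kappa, pi)
    lengths = tree.branch_lengths() * mu_site_per_gen
    probs = _hky_transition_probs(q, pi, lengths)

    states = np.empty((tree.n_nodes, length), dtype=np.int64)
    order = tree.preorder()
    root = order[0]
    states[root] = rng.choice(4, size=length, p=pi)
    for v in order[1:]:
        parent_states = states[tree.node_parent[v]]
        p_rows = probs[v][parent_states]  # (length, 4)
        cdf = np.cumsum(p_rows, axis=1)
        cdf[:, -1] = np.maximum(cdf[:, -1], 1.0)
        u = rng.random(length)
        states[v] = (u[:, None] > cdf).sum(axis=1)

    bases = np.array(list("ACGT"))
    records = []
    for tip in range(tree.n_tips):
        seq = "".join(bases[states[tip]])
        records.append(
            SequenceRecord(f"{sample_prefix}{tip:04d}", tree.tip_populations[tip], seq)
        )
    return SequenceDataset(records, region_label=region_label)


def _stepwise_walk(start: int, n_steps: int, rng: np.random.Generator) -> int:
    """Symmetric +/-1 walk with a reflecting floor at allele 1."""
    if start > n_steps + 1:
        # cannot reach the floor: net displacement suffices
        up = int(rng.binomial(n_steps, 0.5))
        return start + 2 * up - n_steps
    value = start
    for step in rng.integers(0, 2, size=n_steps):
        value += 1 if step else -1
        if value < 1:
            value = 2 - value  # reflect the decrement at the floor
    return value


def apply_smm_mutations(tree: Genealogy, spec: MutationSpec,
                        rng: np.random.Generator,
                        sample_prefix: str = "sim") -> StrDataset:
    """Evolve STR repeat counts down the genealogy under the stepwise model."""
    if spec.model != "smm":
        raise ValidationError("apply_smm_mutations needs an SMM MutationSpec")
    params = spec.smm
    lengths = tree.branch_lengths()
    order = tree.preorder()
    root = order[0]
    n_loci = len(params.locus_names)
    states = np.empty((tree.n_nodes, n_loci), dtype=np.int64)
    states[root] = params.root_allele
    for v in order[1:]:
        parent_states = states[tree.node_parent[v]]
        for l, rate in enumerate(params.rates_per_generation):
            n_mut = rng.poisson(rate * lengths[v])
            if n_mut == 0:
                states[v, l] = parent_states[l]
            else:
                states[v, l] = _stepwise_walk(int(parent_states[l]), int(n_mut), rng)
    records = []
    for tip in range(tree.n_tips):
        records.append(
            StrRecord(
                f"{sample_prefix}{tip:04d}",
                tree.tip_populations[tip],
                tuple(int(x) for x in states[tip]),
            )
        )
    return StrDataset(list(params.locus_names), records)


# ---------------------------------------------------------------------------
# Scenario -> demography -> dataset


#: Backward time beyond which the source deme's size stays constant. Deep
#: enough that results are insensitive to it (the unit floor binds first for
#: the default source size and growth).
SOURCE_GROWTH_HORIZON = 2000.0


def build_demography(spec: ScenarioSpec, drawn_params: dict,
                     backward_literal: bool = False) -> DemographyModel:
    """Concrete demography for one scenario draw.

    ``drawn_params`` must carry ``sink_ne``, ``sink_migration`` and
    ``split_times`` (one per sink), all inside the spec's prior ranges.
    By default the stated source<->sink gene-flow numbers are read as
    forward-time flow and converted to backward lineage-tracing rates by
    swapping direction; ``backward_literal=True`` uses them as backward
    rates unchanged.
    """
    sink_ne = float(drawn_params["sink_ne"])
    sink_m = float(drawn_params["sink_migration"])
    split_times = [float(x) for x in drawn_params["split_times"]]
    lo, hi = spec.sink_ne_range
    if not lo <= sink_ne <= hi:
        raise ValidationError(f"sink_ne {sink_ne} outside prior range {spec.sink_ne_range}")
    lo, hi = spec.sink_migration_range
    if not lo <= sink_m <= hi:
        raise ValidationError(
            f"sink_migration {sink_m} outside prior range {spec.sink_migration_range}"
        )
    if len(split_times) != spec.n_sinks:
        raise ValidationError("one split time per sink required")
    lo, hi = spec.split_time_range
    for st in split_times:
        if not lo <= st <= hi:
            raise ValidationError(f"split time {st} outside prior range {spec.split_time_range}")

    pops = [
        PopulationConfig(
            "source", spec.source_ne, spec.source_growth,
            growth_horizon=SOURCE_GROWTH_HORIZON,
        )
    ]
    for i in range(spec.n_sinks):
        pops.append(PopulationConfig(f"sink{i + 1}", sink_ne, spec.sink_growth))

    n = spec.n_sinks + 1
    mig = np.zeros((n, n))
    if backward_literal:
        source_to_sink_backward = spec.source_to_sink_m
        sink_to_source_backward = spec.sink_to_source_m
    else:
        # forward flow source->sink means sink lineages trace back to source
        source_to_sink_backward = spec.sink_to_source_m
        sink_to_source_backward = spec.source_to_sink_m
    for i in range(1, n):
        mig[i, 0] = source_to_sink_backward
        mig[0, i] = sink_to_source_backward
        for j in range(1, n):
            if i != j:
                mig[i, j] = sink_m

    splits = [
        (f"sink{i + 1}", "source", split_times[i]) for i in range(spec.n_sinks)
    ]
    return DemographyModel(populations=pops, migration=mig, splits=splits)


def simulate_dataset(spec: ScenarioSpec, drawn_params: dict,
                     rng: np.random.Generator,
                     backward_literal: bool = False):
    """Simulate one replicate dataset (sequences or STR profiles).

    Samples ``sample_size_per_sink`` tips in every sink (none in the
    source), then applies the marker's mutation layer.
    """
    model = build_demography(spec, drawn_params, backward_literal=backward_literal)
    sample_sizes = {
        f"sink{i + 1}": spec.sample_size_per_sink for i in range(spec.n_sinks)
    }
    tree = simulate_genealogy(model, sample_sizes, rng)
    if spec.marker == "mtdna":
        mspec = MutationSpec(
            model="hky", hky=HkyParams(length_bp=spec.seq_length_bp)
        )
        return apply_hky_mutations(
            tree, mspec, rng, generation_years=model.generation_years,
            region_label="simulated-mtdna",
        )
    rates = tuple(DEFAULT_STR_RATES.get(locus, 2.0e-3) for locus in spec.str_loci)
    mspec = MutationSpec(
        model="smm", smm=SmmParams(locus_names=tuple(spec.str_loci),
                                   rates_per_generation=rates),
    )
    return apply_smm_mutations(tree, mspec, rng)
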