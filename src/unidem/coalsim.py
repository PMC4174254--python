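"""Haploid structured-coalescent simulator for a serial-founder history.

The demographic model is a fixed six-region topology: an ancestral African
population (growth onset at T1), a single out-of-Africa founder event (T2),
then successive splits of Oceania (T3), Europe (T4), Central vs. East Asia
(T5) and East Asia vs. America (T6), with no migration after divergence.
Each terminal regional branch grows exponentially from its founding size to
its current size; internal (backbone) non-African branches are constant at
the out-of-Africa founder size; before T1 the size is constant at the
African founding size.  An optional ME/NA deme (sister to Europe at T4) is
supported so full-panel datasets can be emulated.

Simulation runs in reverse time with exact inversion of the integrated
coalescence intensity within exponential epochs.  Mutations follow the
infinite-sites model with per-partition yearly rates.

Times in the public API are in years; internally everything is in
generations (``generation_time`` years per generation, default 25).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from numba import njit

from .haplotype_io import HaplotypeMatrix, Site

__all__ = [
    "REGION_ORDER",
    "DemographicModel",
    "LocusSpec",
    "SampleConfig",
    "PriorSpec",
    "Genealogy",
    "mtdna_locus",
    "nry_locus",
    "draw_parameters",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_aggregates",
    "stats_from_aggregates",
    "SIZE_PARAM_NAMES",
    "TIME_PARAM_NAMES",
    "model_from_params",
]

#: Deme order used throughout the simulator (index = deme id).
REGION_ORDER = ("Africa", "Oceania", "Europe", "Central Asia", "East Asia", "America")
MENA = "ME/NA"

TIME_PARAM_NAMES = ("T1", "T2", "T3", "T4", "T5", "T6")
SIZE_PARAM_NAMES = (
    "N_anc_africa",
    "N_ooa",
    "N_anc_Oceania",
    "N_anc_Europe",
    "N_anc_Central Asia",
    "N_anc_East Asia",
    "N_anc_America",
    "N_cur_Africa",
    "N_cur_Oceania",
    "N_cur_Europe",
    "N_cur_Central Asia",
    "N_cur_East Asia",
    "N_cur_America",
)

# NRY mutation rates, substitutions/site/year
NRY_RATE_FAST = 1.00e-9
NRY_RATE_SLOW = 6.17e-10
NRY_RATE_AVERAGE = (NRY_RATE_FAST + NRY_RATE_SLOW) / 2.0
NRY_CALLABLE_LENGTH = 501_108

# mtDNA partitions: (length bp, substitutions/site/year)
MTDNA_NONCODING = (1_122, 9.883e-8)
MTDNA_CODING = (15_447, 1.708e-8)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DemographicModel:
    """Serial-founder history: event times (years) and effective sizes.

    Sizes are those of the transmitting sex: supply female sizes when
    simulating mtDNA and male sizes for the NRY.
    """

    T1: float
    T2: float
    T3: float
    T4: float
    T5: float
    T6: float
    N_anc_africa: float
    N_ooa: float
    N_anc: dict[str, float]  # founding sizes per non-African region
    N_cur: dict[str, float]  # current sizes per region (including Africa)
    generation_time: float = 25.0

    def __post_init__(self) -> None:
        times = [self.T1, self.T2, self.T3, self.T4, self.T5, self.T6]
        if not all(a > b for a, b in zip(times, times[1:])) or times[-1] <= 0:
            raise ValueError(f"event times must satisfy T1 > ... > T6 > 0, got {times}")
        sizes = [self.N_anc_africa, self.N_ooa, *self.N_anc.values(),
                 *self.N_cur.values()]
        if any(s < 1 for s in sizes):
            raise ValueError("all effective sizes must be >= 1")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")

    @property
    def times_years(self) -> np.ndarray:
        return np.array([self.T1, self.T2, self.T3, self.T4, self.T5, self.T6])


@dataclasses.dataclass
class LocusSpec:
    """Locus label plus (length bp, substitutions/site/year) partitions."""

    label: str
    partitions: list[tuple[int, float]]

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValueError("locus needs at least one partition")
        for length, rate in self.partitions:
            if length <= 0 or rate <= 0:
                raise ValueError("partition lengths and rates must be positive")

    @property
    def total_length(self) -> int:
        return sum(length for length, _ in self.partitions)

    def mu_per_generation(self, generation_time: float) -> float:
        """Total locus mutation rate per generation."""
        return sum(l * r for l, r in self.partitions) * generation_time


def mtdna_locus(single_rate: float | None = None) -> LocusSpec:
    """Complete mtDNA genome; two partitions unless a single rate is forced."""
    if single_rate is not None:
        length = MTDNA_NONCODING[0] + MTDNA_CODING[0]
        return LocusSpec("mtDNA", [(length, single_rate)])
    return LocusSpec("mtDNA", [MTDNA_NONCODING, MTDNA_CODING])


def nry_locus(rate: str | float = "average") -> LocusSpec:
    rates = {"fast": NRY_RATE_FAST, "slow": NRY_RATE_SLOW, "average": NRY_RATE_AVERAGE}
    r = rates[rate] if isinstance(rate, str) else float(rate)
    return LocusSpec("NRY", [(NRY_CALLABLE_LENGTH, r)])


@dataclasses.dataclass
class SampleConfig:
    """Per-region haploid sample counts (present-day samples)."""

    counts: dict[str, int] = dataclasses.field(
        default_factory=lambda: {
            "Africa": 85,
            "Central Asia": 146,
            "East Asia": 162,
            "Europe": 79,
            "Oceania": 17,
            "America": 22,
        }
    )

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("sample counts must be nonnegative")
        if self.total < 2:
            raise ValueError("need at least two samples in total")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        regions = list(REGION_ORDER) + [MENA]
        return np.array([self.counts.get(r, 0) for r in regions], dtype=np.int64)


@dataclasses.dataclass
class PriorSpec:
    """Uniform time priors (years) and log-uniform size priors."""

    time_ranges: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {
            "T1": (100_000.0, 150_000.0),
            "T2": (60_000.0, 100_000.0),
            "T3": (60_000.0, 100_000.0),
            "T4": (40_000.0, 60_000.0),
            "T5": (20_000.0, 40_000.0),
            "T6": (10_000.0, 20_000.0),
        }
    )
    founding_range: tuple[float, float] = (1.0, 1.0e4)
    current_range: tuple[float, float] = (1.0e2, 2.0e5)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.time_ranges.items():
            if not lo < hi:
                raise ValueError(f"empty prior range for {name}")
        for lo, hi in (self.founding_range, self.current_range):
            if not 0 < lo < hi:
                raise ValueError("size prior ranges must satisfy 0 < lo < hi")


def draw_parameters(
    priors: PriorSpec, rng: np.random.Generator, generation_time: float = 25.0
) -> DemographicModel:
    """One joint prior draw; time draws violating T2 > T3 (or any ordering)
    are rejected and redrawn."""
    names = list(TIME_PARAM_NAMES)
    for _ in range(100_000):
        t = [rng.uniform(*priors.time_ranges[n]) for n in names]
        if all(a > b for a, b in zip(t, t[1:])):
            break
    else:  # pragma: no cover - astronomically unlikely with sane priors
        raise RuntimeError("could not draw ordered divergence times")
    flo, fhi = np.log(priors.founding_range)
    clo, chi = np.log(priors.current_range)
    founding = {r: float(np.exp(rng.uniform(flo, fhi))) for r in
                ("africa", "ooa", *REGION_ORDER[1:])}
    current = {r: float(np.exp(rng.uniform(clo, chi))) for r in REGION_ORDER}
    return DemographicModel(
        T1=t[0], T2=t[1], T3=t[2], T4=t[3], T5=t[4], T6=t[5],
        N_anc_africa=founding["africa"],
        N_ooa=founding["ooa"],
        N_anc={r: founding[r] for r in REGION_ORDER[1:]},
        N_cur=current,
        generation_time=generation_time,
    )


def model_from_params(
    times_years: Sequence[float],
    sizes: Sequence[float],
    generation_time: float = 25.0,
) -> DemographicModel:
    """Build a model from the canonical 6-time + 13-size parameter vectors."""
    s = dict(zip(SIZE_PARAM_NAMES, sizes))
    return DemographicModel(
        *[float(x) for x in times_years],
        N_anc_africa=s["N_anc_africa"],
        N_ooa=s["N_ooa"],
        N_anc={r: s[f"N_anc_{r}"] for r in REGION_ORDER[1:]},
        N_cur={r: s[f"N_cur_{r}"] for r in REGION_ORDER},
        generation_time=generation_time,
    )


def size_params_of(model: DemographicModel) -> np.ndarray:
    vals = {
        "N_anc_africa": model.N_anc_africa,
        "N_ooa": model.N_ooa,
        **{f"N_anc_{r}": model.N_anc[r] for r in REGION_ORDER[1:]},
        **{f"N_cur_{r}": model.N_cur[r] for r in REGION_ORDER},
    }
    return np.array([vals[n] for n in SIZE_PARAM_NAMES])


# ---------------------------------------------------------------------------
# Epoch table construction (Python) and event loop (numba)
# ---------------------------------------------------------------------------

N_DEMES = 7  # six regions + optional ME/NA
_BIG = 1.0e300


def _epoch_tables(model: DemographicModel, mena_sizes: tuple[float, float] | None):
    """Piecewise size functions N_d(t) = A * exp(-beta * t) per epoch/deme.

    Epoch boundaries (generations, backward from present):
    [0, t6, t5, t4, t3, t2, t1, inf).  ``merge_dst[e, d]`` moves deme d's
    lineages into the destination deme when time crosses into epoch e.
    """
    g = model.generation_time
    t1, t2, t3, t4, t5, t6 = (x / g for x in
                              (model.T1, model.T2, model.T3, model.T4,
                               model.T5, model.T6))
    boundaries = np.array([0.0, t6, t5, t4, t3, t2, t1, _BIG])
    n_epochs = 7
    active = np.zeros((n_epochs, N_DEMES), dtype=np.int64)
    A = np.ones((n_epochs, N_DEMES))
    beta = np.zeros((n_epochs, N_DEMES))
    merge_dst = np.full((n_epochs, N_DEMES), -1, dtype=np.int64)

    def growth(region_idx: int, name: str, tau: float, epochs: range) -> None:
        nc = model.N_cur[name]
        na = model.N_anc[name] if name != "Africa" else model.N_anc_africa
        b = np.log(nc / na) / tau
        for e in epochs:
            active[e, region_idx] = 1
            A[e, region_idx] = nc
            beta[e, region_idx] = b

    growth(0, "Africa", t1, range(0, 6))
    active[6, 0] = 1
    A[6, 0] = model.N_anc_africa
    growth(1, "Oceania", t3, range(0, 4))
    growth(2, "Europe", t4, range(0, 3))
    growth(3, "Central Asia", t5, range(0, 2))
    for e in (2, 3, 4):  # Central Asia hosts the non-African backbone
        active[e, 3] = 1
        A[e, 3] = model.N_ooa
        beta[e, 3] = 0.0
    growth(4, "East Asia", t5, range(0, 2))
    growth(5, "America", t6, range(0, 1))
    if mena_sizes is not None:
        na, nc = mena_sizes
        b = np.log(nc / na) / t4
        for e in range(0, 3):
            active[e, 6] = 1
            A[e, 6] = nc
            beta[e, 6] = b
    merge_dst[1, 5] = 4       # t6: America -> East Asia
    merge_dst[2, 4] = 3       # t5: East Asia -> Asia backbone
    merge_dst[3, 2] = 3       # t4: Europe -> backbone
    merge_dst[3, 6] = 3       # t4: ME/NA -> backbone
    merge_dst[4, 1] = 3       # t3: Oceania -> backbone
    merge_dst[5, 3] = 0       # t2: backbone -> Africa
    return boundaries, active, A, beta, merge_dst


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _sim_core(sample_counts, boundaries, active, A, beta, merge_dst):
    n_demes = sample_counts.shape[0]
    n = 0
    for d in range(n_demes):
        n += sample_counts[d]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)
    members = np.full((n_demes, n), -1, dtype=np.int64)
    cnt = np.zeros(n_demes, dtype=np.int64)
    idx = 0
    for d in range(n_demes):
        for _ in range(sample_counts[d]):
            members[d, cnt[d]] = idx
            cnt[d] += 1
            idx += 1
    t = 0.0
    e = 0
    nxt = n
    total = n
    n_epochs = boundaries.shape[0] - 1
    while total > 1:
        best_t = _BIG
        best_d = -1
        for d in range(n_demes):
            k = cnt[d]
            if k >= 2 and active[e, d] == 1:
                rate0 = k * (k - 1) / (2.0 * A[e, d])
                E = np.random.exponential()
                b = beta[e, d]
                if b == 0.0:
                    cand = t + E / rate0
                else:
                    arg = np.exp(b * t) + E * b / rate0
                    cand = np.log(arg) / b if arg > 0.0 else _BIG
                if cand < best_t:
                    best_t = cand
                    best_d = d
        if e < n_epochs - 1 and best_t >= boundaries[e + 1]:
            t = boundaries[e + 1]
            e += 1
            for d in range(n_demes):
                dst = merge_dst[e, d]
                if dst >= 0 and cnt[d] > 0:
                    for i in range(cnt[d]):
                        members[dst, cnt[dst]] = members[d, i]
                        cnt[dst] += 1
                    cnt[d] = 0
            continue
        # coalescence in deme best_d at time best_t
        k = cnt[best_d]
        i = np.random.randint(0, k)
        j = np.random.randint(0, k - 1)
        if j >= i:
            j += 1
        a_node = members[best_d, i]
        b_node = members[best_d, j]
        parent[a_node] = nxt
        parent[b_node] = nxt
        node_time[nxt] = best_t
        hi = i if i > j else j
        lo = j if i > j else i
        members[best_d, hi] = members[best_d, k - 1]
        members[best_d, lo] = members[best_d, k - 2]
        members[best_d, k - 2] = nxt
        cnt[best_d] = k - 1
        t = best_t
        nxt += 1
        total -= 1
    return parent, node_time


@njit(cache=True)
def _region_counts(parent, leaf_regions, n_regions):
    n_nodes = parent.shape[0]
    n_leaves = (n_nodes + 1) // 2
    counts = np.zeros((n_nodes, n_regions), dtype=np.int64)
    for v in range(n_leaves):
        counts[v, leaf_regions[v]] += 1
    for v in range(n_nodes):
        p = parent[v]
        if p >= 0:
            for r in range(n_regions):
                counts[p, r] += counts[v, r]
    return counts


@njit(cache=True)
def _accumulate_aggregates(parent, node_time, counts, region_sizes, mu_gen):
    """Poisson mutations per branch -> per-region site-count aggregates.

    Returns (S per region, within-region pair-difference sums, between-region
    pair-difference sums) summed over realized mutations.
    """
    nreg = region_sizes.shape[0]
    S = np.zeros(nreg, dtype=np.int64)
    pw = np.zeros(nreg, dtype=np.float64)
    pairD = np.zeros((nreg, nreg), dtype=np.float64)
    n_nodes = parent.shape[0]
    for v in range(n_nodes):
        p = parent[v]
        if p < 0:
            continue
        bl = node_time[p] - node_time[v]
        if bl <= 0.0:
            continue
        m_v = np.random.poisson(bl * mu_gen)
        if m_v == 0:
            continue
        for r in range(nreg):
            c = counts[v, r]
            nr = region_sizes[r]
            if 0 < c < nr:
                S[r] += m_v
            pw[r] += m_v * c * (nr - c)
            for r2 in range(r + 1, nreg):
                c2 = counts[v, r2]
                pairD[r, r2] += m_v * (
                    c * (region_sizes[r2] - c2) + c2 * (nr - c)
                )
    return S, pw, pairD


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Genealogy:
    """Coalescent tree: parent links, node times (generations), leaf regions."""

    parent: np.ndarray
    node_time: np.ndarray
    leaf_regions: np.ndarray       # deme index per leaf
    region_names: list[str]
    generation_time: float

    @property
    def n_leaves(self) -> int:
        return (len(self.parent) + 1) // 2

    @property
    def leaf_labels(self) -> list[str]:
        return [f"s{i}" for i in range(self.n_leaves)]

    @property
    def tmrca(self) -> float:
        """Time to the most recent common ancestor, generations."""
        return float(self.node_time[-1])

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(len(self.parent))
        has_parent = self.parent >= 0
        bl[has_parent] = (
            self.node_time[self.parent[has_parent]] - self.node_time[has_parent]
        )
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def mean_pairwise_time(self) -> float:
        """Mean over sample pairs of the path length separating them."""
        n = self.n_leaves
        counts = _region_counts(
            self.parent, np.zeros(n, dtype=np.int64), 1
        )[:, 0]
        bl = self.branch_lengths()
        pair_sum = float(np.sum(bl * counts * (n - counts)))
        return pair_sum / (n * (n - 1) / 2.0)

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in self.parent]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch


def simulate_genealogy(
    model: DemographicModel,
    cfg: SampleConfig,
    seed: int,
    mena_sizes: tuple[float, float] | None = None,
) -> Genealogy:
    """Simulate one genealogy of the configured samples under the model."""
    counts = cfg.as_array()
    if counts[6] > 0 and mena_sizes is None:
        raise ValueError("ME/NA samples requested but no ME/NA sizes supplied")
    boundaries, active, A, beta, merge_dst = _epoch_tables(model, mena_sizes)
    leaf_regions = np.repeat(np.arange(N_DEMES), counts).astype(np.int64)
    _seed_rng(seed % (2**31 - 1))
    if counts.sum() == 1:
        return Genealogy(
            parent=np.array([-1], dtype=np.int64),
            node_time=np.zeros(1),
            leaf_regions=leaf_regions,
            region_names=list(REGION_ORDER) + [MENA],
            generation_time=model.generation_time,
        )
    parent, node_time = _sim_core(counts, boundaries, active, A, beta, merge_dst)
    return Genealogy(
        parent=parent,
        node_time=node_time,
        leaf_regions=leaf_regions,
        region_names=list(REGION_ORDER) + [MENA],
        generation_time=model.generation_time,
    )


def drop_mutations(
    genealogy: Genealogy,
    locus: LocusSpec,
    generation_time: float | None = None,
    seed: int = 0,
    ref_sequence: str | None = None,
) -> HaplotypeMatrix:
    """Scatter infinite-sites mutations on the genealogy -> haplotype matrix.

    Per partition the mutation count on each branch is Poisson with mean
    branch length (generations) x yearly rate x generation time x length;
    every mutation hits a new site.  If ``ref_sequence`` is supplied, the
    reference allele at each position is read from it and the alternative is
    the next base in A->C->G->T cyclic order.
    """
    g = generation_time or genealogy.generation_time
    rng = np.random.default_rng(seed)
    bl = genealogy.branch_lengths()
    n = genealogy.n_leaves
    ch = genealogy.children()
    site_entries: list[tuple[int, int]] = []  # (global position, branch node)
    offset = 0
    for length, rate in locus.partitions:
        mu_branch = bl * rate * g * length
        m_per_branch = rng.poisson(mu_branch)
        total = int(m_per_branch.sum())
        if total > length:
            raise ValueError(
                f"infinite-sites violated: {total} mutations on a "
                f"{length} bp partition"
            )
        positions = np.sort(rng.choice(length, size=total, replace=False))
        k = 0
        for v in np.flatnonzero(m_per_branch):
            for _ in range(int(m_per_branch[v])):
                site_entries.append((offset + int(positions[k]) + 1, int(v)))
                k += 1
        offset += length
    site_entries.sort()
    genotypes = np.zeros((n, len(site_entries)), dtype=np.int8)
    for j, (_, v) in enumerate(site_entries):
        # mark all leaves below the mutated branch as carrying the derived allele
        stack = [v]
        while stack:
            u = stack.pop()
            if u < n:
                genotypes[u, j] = 1
            else:
                stack.extend(ch[u])
    bases = "ACGT"
    sites = []
    for pos, _ in site_entries:
        if ref_sequence is not None:
            ref = ref_sequence[pos - 1]
            alt = bases[(bases.index(ref) + 1) % 4]
        else:
            ref, alt = "A", "G"
        sites.append(Site(position=pos, ref_allele=ref, alt_allele=alt))
    return HaplotypeMatrix(
        sample_ids=genealogy.leaf_labels,
        sites=sites,
        genotypes=genotypes,
        locus_label=locus.label,
    )


def simulate_aggregates(
    model: DemographicModel,
    cfg: SampleConfig,
    locus: LocusSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fast path: simulate and return per-region site-count aggregates.

    Returns (S per region, within-region pair-difference sums pw, pairwise
    between-region difference sums pairD, region sample sizes).  Mutations
    are realized (Poisson per branch) but never materialized as a matrix;
    all downstream summary statistics are functions of these aggregates.
    """
    counts = cfg.as_array()
    boundaries, active, A, beta, merge_dst = _epoch_tables(model, None)
    _seed_rng(seed % (2**31 - 1))
    parent, node_time = _sim_core(counts, boundaries, active, A, beta, merge_dst)
    leaf_regions = np.repeat(np.arange(N_DEMES), counts).astype(np.int64)
    node_counts = _region_counts(parent, leaf_regions, N_DEMES)
    mu_gen = locus.mu_per_generation(model.generation_time)
    S, pw, pairD = _accumulate_aggregates(
        parent, node_time, node_counts, counts, mu_gen
    )
    return S, pw, pairD, counts


def stats_from_aggregates(
    S: np.ndarray,
    pw: np.ndarray,
    pairD: np.ndarray,
    region_sizes: np.ndarray,
    regions: Sequence[str] = REGION_ORDER,
) -> np.ndarray:
    """Summary-statistic vector from site-count aggregates.

    Layout (fixed): per region S, mpd, Tajima's D (len 3R); pairwise Phi_ST
    for region pairs in order (len R(R-1)/2); then the two variance
    components of a 2-level AMOVA of Africa vs. pooled non-Africa.
    Undefined entries (n < 2, or D with S = 0, or Phi with no variation)
    are NaN sentinels.
    """
    from .popgen_stats import tajimas_d_from_counts

    R = len(regions)
    out = []
    mpd = np.full(R, np.nan)
    for r in range(R):
        nr = int(region_sizes[r])
        if nr < 2:
            out.extend([np.nan, np.nan, np.nan])
            continue
        mpd[r] = pw[r] / (nr * (nr - 1) / 2.0)
        d = tajimas_d_from_counts(nr, int(S[r]), mpd[r])
        out.extend([float(S[r]), mpd[r], np.nan if d is None else d])
    for r1 in range(R):
        for r2 in range(r1 + 1, R):
            out.append(_phi_from_sums(
                pw[r1], pw[r2], pairD[r1, r2],
                int(region_sizes[r1]), int(region_sizes[r2]),
            ))
    # AMOVA: Africa vs pooled non-Africa (two populations, 2-level)
    afr = 0
    non = [r for r in range(R) if r != afr]
    w_non = float(sum(pw[r] for r in non))
    for i, r1 in enumerate(non):
        for r2 in non[i + 1:]:
            w_non += float(pairD[min(r1, r2), max(r1, r2)])
    b_cross = float(sum(pairD[min(afr, r), max(afr, r)] for r in non))
    n_afr = int(region_sizes[afr])
    n_non = int(sum(region_sizes[r] for r in non))
    sig_a, sig_c = _amova_components_from_sums(
        pw[afr], w_non, b_cross, n_afr, n_non
    )
    out.extend([sig_a, sig_c])
    return np.array(out, dtype=np.float64)


def _amova_components_from_sums(w1, w2, between, n1, n2):
    """Two-population AMOVA variance components from pair-difference sums."""
    N = n1 + n2
    if n1 < 2 or n2 < 2:
        return np.nan, np.nan
    ssd_total = (w1 + w2 + between) / N
    ssd_within = w1 / n1 + w2 / n2
    ssd_among = ssd_total - ssd_within
    ms_within = ssd_within / (N - 2)
    n_prime = N - (n1**2 + n2**2) / N  # df_among = 1
    sigma_a = (ssd_among - ms_within) / n_prime
    return float(sigma_a), float(ms_within)


def _phi_from_sums(w1, w2, between, n1, n2):
    sigma_a, sigma_c = _amova_components_from_sums(w1, w2, between, n1, n2)
    if not np.isfinite(sigma_a):
        return np.nan
    total = sigma_a + sigma_c
    if total == 0:
        return np.nan
    return float(sigma_a / total)


def stat_labels(regions: Sequence[str] = REGION_ORDER) -> list[str]:
    labels = []
    for r in regions:
        labels.extend([f"S_{r}", f"mpd_{r}", f"D_{r}"])
    for i, r1 in enumerate(regions):
        for r2 in list(regions)[i + 1:]:
            labels.append(f"phi_{r1}|{r2}")
    labels.extend(["amova_among", "amova_within"])
    return labels
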