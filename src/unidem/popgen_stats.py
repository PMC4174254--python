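"""Diversity and differentiation statistics for haploid sequence data.

Implements the classical estimators for a non-recombining locus: haplotype
diversity H, segregating sites S, mean pairwise differences (mpd) with
Tajima's variance-based SE, per-site nucleotide diversity pi = mpd/L,
Watterson's theta_S, Tajima's D, distance-based AMOVA (2- and 3-level) with
Phi-statistics and permutation tests, the NRY/mtDNA mpd-ratio resampling
null, Mantel tests, and great-circle distances.

All distance-based statistics use the pairwise-difference count as the
squared inter-haplotype distance (the molecular-variance convention), so a
2-level AMOVA on two populations reproduces pairwise Phi_ST exactly.
"""

from __future__ import annotations

import dataclasses
import functools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .haplotype_io import MISSING, HaplotypeMatrix, SampleTable

__all__ = [
    "DiversityStats",
    "AmovaResult",
    "MpdRatioResult",
    "DistanceMatrix",
    "diversity_stats",
    "pairwise_differences",
    "amova",
    "pairwise_phist",
    "mpd_ratio_resample",
    "mantel",
    "great_circle_distances",
    "tajimas_d_from_counts",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Basic containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DiversityStats:
    n: int
    H: float
    S: int
    mpd: float
    mpd_se: float
    pi: float
    pi_se: float
    theta_S: float          # per locus
    theta_S_per_site: float
    tajimas_D: float | None  # None when S == 0 (undefined)


@dataclasses.dataclass
class AmovaResult:
    design: str                       # "2-level" or "3-level"
    components: dict[str, float]      # sigma2_a / sigma2_b / sigma2_c
    percentages: dict[str, float]     # same keys, summing to 100
    phi: dict[str, float]             # Phi_ST (+ Phi_SC, Phi_CT for 3-level)
    p_values: dict[str, float]
    df: dict[str, int]
    ssd: dict[str, float]


@dataclasses.dataclass
class MpdRatioResult:
    group: str
    n_group: int
    observed_ratio: float
    null_ratios: np.ndarray
    p_value: float


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-9).any():
            raise ValueError("distance matrix must be nonnegative")
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=4096)
def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "e1": e1, "e2": e2}


def tajimas_d_from_counts(n: int, S: int, mpd: float) -> float | None:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs."""
    if S == 0:
        return None
    k = _tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:  # degenerate (e.g. n = 2): variance formula collapses
        return None
    return float((mpd - S / k["a1"]) / np.sqrt(var))


def pairwise_differences(m: HaplotypeMatrix) -> np.ndarray:
    """Pairwise difference counts with pairwise deletion over non-N sites."""
    G = m.genotypes
    obs = (G != MISSING).astype(np.float64)
    Gf = np.where(G == 1, 1.0, 0.0) * obs
    both = obs @ obs.T
    same = Gf @ Gf.T + (obs - Gf) @ (obs - Gf).T
    d = both - same
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def diversity_stats(m: HaplotypeMatrix, L: float) -> DiversityStats:
    """Standard diversity summary for one locus/population sample.

    H uses the unbiased estimator n/(n-1) (1 - sum p_i^2) over haplotype
    frequencies; mpd is the mean Hamming distance over all sample pairs
    (pairwise deletion); SEs follow Tajima's total variance formulas; pi is
    mpd divided by the callable length L.
    """
    n = m.n_samples
    if n < 2:
        raise ValueError("diversity statistics require at least 2 samples")
    G = m.genotypes
    variable = np.zeros(m.n_sites, dtype=bool)
    for j in range(m.n_sites):
        col = G[:, j]
        obs = col[col != MISSING]
        variable[j] = obs.size > 0 and (obs != obs[0]).any()
    S = int(variable.sum())
    D = pairwise_differences(m)
    iu = np.triu_indices(n, k=1)
    mpd = float(D[iu].mean())
    # haplotype diversity over full-row patterns
    _, counts = np.unique(G, axis=0, return_counts=True)
    p = counts / n
    H = float(n / (n - 1) * (1.0 - np.sum(p**2)))
    k = _tajima_constants(n)
    mpd_var = k["b1"] * mpd + k["b2"] * mpd**2
    mpd_se = float(np.sqrt(mpd_var))
    theta_S = S / k["a1"]
    return DiversityStats(
        n=n,
        H=H,
        S=S,
        mpd=mpd,
        mpd_se=mpd_se,
        pi=mpd / L,
        pi_se=mpd_se / L,
        theta_S=float(theta_S),
        theta_S_per_site=float(theta_S / L),
        tajimas_D=tajimas_d_from_counts(n, S, mpd),
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _ssd(D: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared distances within a set, scaled by its size."""
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _amova_2level(D: np.ndarray, pops: np.ndarray) -> dict:
    N = len(pops)
    labels, inverse = np.unique(pops, return_inverse=True)
    P = len(labels)
    sizes = np.bincount(inverse)
    ssd_total = float(D.sum() / (2.0 * N))
    ssd_within = sum(
        _ssd(D, np.flatnonzero(inverse == p)) for p in range(P)
    )
    ssd_among = ssd_total - ssd_within
    df_among, df_within = P - 1, N - P
    ms_within = ssd_within / df_within
    n_prime = (N - np.sum(sizes**2) / N) / (P - 1)
    sigma_c = ms_within
    sigma_a = (ssd_among / df_among - ms_within) / n_prime
    total = sigma_a + sigma_c
    phi_st = sigma_a / total if total != 0 else 0.0
    return {
        "sigma_a": sigma_a,
        "sigma_c": sigma_c,
        "phi_st": phi_st,
        "ssd_total": ssd_total,
        "ssd_among": ssd_among,
        "ssd_within": ssd_within,
        "df_among": df_among,
        "df_within": df_within,
    }


def _amova_3level(D: np.ndarray, pops: np.ndarray, groups: np.ndarray) -> dict:
    N = len(pops)
    pop_labels, pop_inv = np.unique(pops, return_inverse=True)
    P = len(pop_labels)
    grp_of_pop = {}
    for p_lab, g_lab in zip(pops, groups):
        if p_lab in grp_of_pop and grp_of_pop[p_lab] != g_lab:
            raise ValueError(f"population {p_lab!r} appears in several groups")
        grp_of_pop[p_lab] = g_lab
    grp_labels = sorted(set(groups))
    G = len(grp_labels)
    pops_per_group = {
        g: [p for p in pop_labels if grp_of_pop[p] == g] for g in grp_labels
    }
    for g, ps in pops_per_group.items():
        if len(ps) < 2:
            raise ValueError(f"group {g!r} has fewer than two populations")
    n_p = {p: int(np.sum(pops == p)) for p in pop_labels}
    n_g = {g: int(np.sum(groups == g)) for g in grp_labels}
    ssd_total = float(D.sum() / (2.0 * N))
    ssd_wp = sum(_ssd(D, np.flatnonzero(pops == p)) for p in pop_labels)
    ssd_wg = sum(_ssd(D, np.flatnonzero(groups == g)) for g in grp_labels)
    ssd_ap = ssd_wg - ssd_wp         # among populations within groups
    ssd_ag = ssd_total - ssd_wg      # among groups
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap / df_ap
    ms_ag = ssd_ag / df_ag
    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in pops_per_group[g]) / n_g[g] for g in grp_labels
    )
    n1 = (N - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - sum(n_p[p] ** 2 for p in pop_labels) / N) / (G - 1)
    n3 = (N - sum(n_g[g] ** 2 for g in grp_labels) / N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    return {
        "sigma_a": sigma_a,
        "sigma_b": sigma_b,
        "sigma_c": sigma_c,
        "phi_st": (sigma_a + sigma_b) / total,
        "phi_ct": sigma_a / total,
        "phi_sc": sigma_b / (sigma_b + sigma_c),
        "ssd_total": ssd_total,
        "ssd_ag": ssd_ag,
        "ssd_ap": ssd_ap,
        "ssd_wp": ssd_wp,
        "df_ag": df_ag,
        "df_ap": df_ap,
        "df_wp": df_wp,
    }


def amova(
    m: HaplotypeMatrix,
    populations: Sequence[str],
    groups: Sequence[str] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    distances: np.ndarray | None = None,
) -> AmovaResult:
    """Distance-based AMOVA with pairwise-difference squared distances.

    ``groups`` selects the 3-level design (groups / populations-in-groups /
    within); permutation tests follow the standard within-level schemes:
    individuals among populations (Phi_ST, Phi_SC within groups) and whole
    populations among groups (Phi_CT).  Negative variance components are
    retained, not clamped.
    """
    pops = np.asarray(list(populations))
    if len(pops) != m.n_samples:
        raise ValueError("one population label per sample required")
    D = pairwise_differences(m) if distances is None else np.asarray(distances)
    rng = np.random.default_rng(seed)
    if groups is None:
        res = _amova_2level(D, pops)
        comp = {"sigma_a": res["sigma_a"], "sigma_c": res["sigma_c"]}
        phi = {"phi_st": res["phi_st"]}
        pvals = {}
        if n_permutations > 0:
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(len(pops))
                r = _amova_2level(D, pops[perm])
                count += r["phi_st"] >= res["phi_st"]
            pvals["phi_st"] = (count + 1) / (n_permutations + 1)
        total = sum(comp.values())
        pct = {k: 100.0 * v / total for k, v in comp.items()}
        return AmovaResult(
            design="2-level",
            components=comp,
            percentages=pct,
            phi=phi,
            p_values=pvals,
            df={"among": res["df_among"], "within": res["df_within"]},
            ssd={
                "total": res["ssd_total"],
                "among": res["ssd_among"],
                "within": res["ssd_within"],
            },
        )
    grps = np.asarray(list(groups))
    if len(grps) != m.n_samples:
        raise ValueError("one group label per sample required")
    res = _amova_3level(D, pops, grps)
    comp = {
        "sigma_a": res["sigma_a"],
        "sigma_b": res["sigma_b"],
        "sigma_c": res["sigma_c"],
    }
    phi = {"phi_st": res["phi_st"], "phi_sc": res["phi_sc"], "phi_ct": res["phi_ct"]}
    pvals = {}
    if n_permutations > 0:
        c_st = c_sc = c_ct = 0
        pop_labels = np.unique(pops)
        grp_of_pop = {p: grps[pops == p][0] for p in pop_labels}
        for _ in range(n_permutations):
            # Phi_ST: individuals among populations (across everything)
            perm = rng.permutation(len(pops))
            r = _amova_3level(D, pops[perm], grps[perm])
            c_st += r["phi_st"] >= res["phi_st"]
            # Phi_SC: individuals among populations within their group
            pops_sc = pops.copy()
            for g in np.unique(grps):
                idx = np.flatnonzero(grps == g)
                pops_sc[idx] = pops_sc[idx[rng.permutation(len(idx))]]
            r = _amova_3level(D, pops_sc, grps)
            c_sc += r["phi_sc"] >= res["phi_sc"]
            # Phi_CT: whole populations among groups
            perm_pops = rng.permutation(pop_labels)
            remap = dict(zip(perm_pops, [grp_of_pop[p] for p in pop_labels]))
            grps_ct = np.asarray([remap[p] for p in pops])
            try:
                r = _amova_3level(D, pops, grps_ct)
            except ValueError:  # degenerate permuted stratum
                continue
            c_ct += r["phi_ct"] >= res["phi_ct"]
        pvals = {
            "phi_st": (c_st + 1) / (n_permutations + 1),
            "phi_sc": (c_sc + 1) / (n_permutations + 1),
            "phi_ct": (c_ct + 1) / (n_permutations + 1),
        }
    total = sum(comp.values())
    pct = {k: 100.0 * v / total for k, v in comp.items()}
    return AmovaResult(
        design="3-level",
        components=comp,
        percentages=pct,
        phi=phi,
        p_values=pvals,
        df={"among_groups": res["df_ag"], "among_pops": res["df_ap"],
            "within": res["df_wp"]},
        ssd={"total": res["ssd_total"], "among_groups": res["ssd_ag"],
             "among_pops": res["ssd_ap"], "within": res["ssd_wp"]},
    )


def pairwise_phist(
    m: HaplotypeMatrix,
    populations: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise Phi_ST between populations via 2-level AMOVA on each pair.

    Populations with fewer than two samples are excluded with a warning.
    Negative estimates are retained.  P-values permute individuals between
    the two populations of each pair.
    """
    pops = np.asarray(list(populations))
    labels = [str(p) for p in pd.unique(pops)]
    kept = []
    for p in labels:
        if int(np.sum(pops == p)) >= 2:
            kept.append(p)
        else:
            warnings.warn(f"population {p!r} has n<2; excluded from Phi_ST")
    D_full = pairwise_differences(m)
    k = len(kept)
    phi = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.flatnonzero(np.isin(pops, [kept[i], kept[j]]))
            sub_pops = pops[idx]
            D = D_full[np.ix_(idx, idx)]
            res = _amova_2level(D, sub_pops)
            phi[i, j] = phi[j, i] = res["phi_st"]
            p = np.nan
            if n_permutations > 0:
                count = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(len(sub_pops))
                    count += _amova_2level(D, sub_pops[perm])["phi_st"] >= res["phi_st"]
                p = (count + 1) / (n_permutations + 1)
            pval[i, j] = pval[j, i] = p
            rows.append((kept[i], kept[j], res["phi_st"], p))
    table = pd.DataFrame(rows, columns=["pop1", "pop2", "phi_st", "p_value"])
    # Phi_ST can be slightly negative; shift is NOT applied to estimates, but
    # the DistanceMatrix container requires nonnegative entries, so clip a
    # copy for geometric use and report raw values in the table.
    return DistanceMatrix(labels=kept, values=np.clip(phi, 0.0, None)), table


# ---------------------------------------------------------------------------
# mpd-ratio resampling
# ---------------------------------------------------------------------------

def _mpd_from_indicator(G: np.ndarray, picks: np.ndarray) -> np.ndarray:
    """mpd for each row-subset indicated by the 0/1 matrix ``picks``."""
    k = picks.sum(axis=1)
    C = picks @ G  # derived-allele counts per site
    pair_diffs = (C * (k[:, None] - C)).sum(axis=1)
    return pair_diffs / (k * (k - 1) / 2.0)


def mpd_ratio_resample(
    nry: HaplotypeMatrix,
    mt: HaplotypeMatrix,
    group_members: Sequence[str],
    reps: int = 10000,
    seed: int = 0,
    group: str = "",
) -> MpdRatioResult:
    """Observed mpd_NRY/mpd_mt for a group against a random-resampling null.

    The null redraws N_group individuals (without replacement) from the full
    shared sample universe and recomputes the ratio; the two-sided empirical
    p-value uses the +1 correction.
    """
    if nry.sample_ids != mt.sample_ids:
        raise ValueError("NRY and mtDNA matrices must share the sample universe")
    if (nry.genotypes == MISSING).any() or (mt.genotypes == MISSING).any():
        raise ValueError("mpd-ratio resampling requires complete matrices")
    ids = {s: i for i, s in enumerate(nry.sample_ids)}
    member_idx = np.asarray([ids[s] for s in group_members])
    n_total = len(nry.sample_ids)
    n_group = len(member_idx)
    if n_group < 2:
        raise ValueError("group needs at least 2 members")
    G_nry = (nry.genotypes == 1).astype(np.float32)
    G_mt = (mt.genotypes == 1).astype(np.float32)
    obs_pick = np.zeros((1, n_total), dtype=np.float32)
    obs_pick[0, member_idx] = 1.0
    mpd_mt_obs = _mpd_from_indicator(G_mt, obs_pick)[0]
    if mpd_mt_obs == 0:
        raise ValueError("group mtDNA mpd is zero; ratio undefined")
    observed = float(_mpd_from_indicator(G_nry, obs_pick)[0] / mpd_mt_obs)
    rng = np.random.default_rng(seed)
    null = np.empty(reps, dtype=np.float64)
    chunk = max(1, min(reps, 2000))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        picks = np.zeros((b, n_total), dtype=np.float32)
        for r in range(b):
            picks[r, rng.choice(n_total, size=n_group, replace=False)] = 1.0
        num = _mpd_from_indicator(G_nry, picks)
        den = _mpd_from_indicator(G_mt, picks)
        null[done : done + b] = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
        done += b
    null = null[np.isfinite(null)]
    n_null = len(null)
    p_low = (1 + int(np.sum(null <= observed))) / (n_null + 1)
    p_high = (1 + int(np.sum(null >= observed))) / (n_null + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return MpdRatioResult(
        group=group,
        n_group=n_group,
        observed_ratio=observed,
        null_ratios=null,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Mantel test and geography
# ---------------------------------------------------------------------------

def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, reps: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; p is
    the one-sided (greater) permutation p-value over row/column permutations.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.distance import mantel as skbio_mantel

    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels")
    if len(d1.labels) < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    for d in (d1, d2):
        if np.allclose(d.condensed(), d.condensed()[0]):
            raise ValueError("constant distance matrix: correlation undefined")
    np.random.seed(seed)  # skbio uses the global numpy RNG
    r, p, _ = skbio_mantel(
        SkbioDM(d1.values, d1.labels),
        SkbioDM(d2.values, d2.labels),
        method="pearson",
        permutations=reps,
        alternative="greater",
    )
    return float(r), float(p)


def great_circle_distances(
    table: SampleTable, by: str = "population"
) -> DistanceMatrix:
    """Haversine great-circle distances (km) between group centroids."""
    df = table.table
    groups = []
    coords = []
    for name, sub in df.groupby(by, sort=True):
        lat = sub["latitude"].dropna()
        lon = sub["longitude"].dropna()
        if lat.empty or lon.empty:
            warnings.warn(f"{by} {name!r} lacks coordinates; excluded")
            continue
        groups.append(str(name))
        coords.append((float(lat.iloc[0]), float(lon.iloc[0])))
    lat = np.radians([c[0] for c in coords])
    lon = np.radians([c[1] for c in coords])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=groups, values=d)
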