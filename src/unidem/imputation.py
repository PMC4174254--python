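"""Sequential nearest-haplotype imputation for a non-recombining locus.

Because the locus is completely linked, a missing call can be copied from
the closest haplotype: all sites with no missing data form the initial
reference set; remaining sites are processed in increasing order of missing
count, each missing call is copied from the minimum-Hamming-distance donor
over the current reference set, and a completed site joins the reference
set.  A mask-and-revalidate protocol measures accuracy on complete data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .haplotype_io import MISSING, HaplotypeMatrix

__all__ = ["ImputationResult", "MaskingReport", "impute_missing", "mask_and_validate",
           "draw_missing_counts", "draw_site_weights", "apply_missingness",
           "SITE_CLUSTER_SIGMA"]

#: Lognormal sigma of the per-site missingness weights.  Missing calls in
#: capture data cluster on hard-to-enrich sites; this value is calibrated so
#: that at the default 2.54% overall missingness roughly a quarter of sites
#: stay complete across a 623-sample panel (the study design this package
#: emulates retained 605 of 2,276 sites as a complete reference set).
SITE_CLUSTER_SIGMA = 1.95


@dataclasses.dataclass
class ImputationResult:
    matrix: HaplotypeMatrix          # completed, N-free
    fill_log: pd.DataFrame           # site, sample, imputed allele, donor, distance

    def __post_init__(self) -> None:
        if (self.matrix.genotypes == MISSING).any():
            raise ValueError("completed matrix still contains missing calls")


@dataclasses.dataclass
class MaskingReport:
    replicates: int
    masked_fraction: float
    per_replicate_accuracy: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.per_replicate_accuracy))


def impute_missing(m: HaplotypeMatrix) -> ImputationResult:
    """Fill every N by copying from the nearest donor haplotype.

    Ties among equidistant donors resolve to the majority allele among them;
    an exact tie falls back to the donor earliest in sample order.  Distances
    are maintained incrementally over the growing reference set.
    """
    G = m.genotypes.copy()
    n, S = G.shape
    missing_per_site = (G == MISSING).sum(axis=0)
    if S and not (missing_per_site == 0).any():
        raise ValueError("imputation requires at least one site with no missing data")
    if (missing_per_site == n).any():
        bad = np.flatnonzero(missing_per_site == n)
        raise ValueError(f"sites with all samples missing cannot be imputed: "
                         f"{[m.sites[j].position for j in bad[:5]]}")
    ref_sites = np.flatnonzero(missing_per_site == 0)
    # pairwise Hamming distances over the reference set
    R = G[:, ref_sites].astype(np.float32)
    dist = _hamming(R)
    order = [
        int(j)
        for j in sorted(
            np.flatnonzero(missing_per_site > 0),
            key=lambda j: (missing_per_site[j], m.sites[j].position),
        )
    ]
    log_rows: list[tuple] = []
    for j in order:
        col = G[:, j]
        miss = np.flatnonzero(col == MISSING)
        donors = np.flatnonzero(col != MISSING)
        for i in miss:
            d = dist[i, donors]
            dmin = d.min()
            nearest = donors[d == dmin]
            alleles = col[nearest]
            votes1 = int((alleles == 1).sum())
            votes0 = int((alleles == 0).sum())
            if votes1 > votes0:
                allele = 1
            elif votes0 > votes1:
                allele = 0
            else:
                allele = int(col[nearest[0]])
            donor = int(nearest[0])
            G[i, j] = allele
            log_rows.append(
                (m.sites[j].position, m.sample_ids[i], allele,
                 m.sample_ids[donor], float(dmin))
            )
        # completed site joins the reference set
        gj = G[:, j].astype(np.float32)
        dist += np.abs(gj[:, None] - gj[None, :])
    completed = HaplotypeMatrix(
        sample_ids=list(m.sample_ids),
        sites=list(m.sites),
        genotypes=G,
        locus_label=m.locus_label,
    )
    fill_log = pd.DataFrame(
        log_rows, columns=["position", "sample_id", "allele", "donor_id", "distance"]
    )
    return ImputationResult(matrix=completed, fill_log=fill_log)


def _hamming(R: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between rows of a complete 0/1 matrix."""
    ones = R @ R.T
    zeros = (1.0 - R) @ (1.0 - R.T)
    return R.shape[1] - ones - zeros


def draw_missing_counts(
    n_samples: int,
    n_sites: int,
    fraction: float,
    rng: np.random.Generator,
    counts_pool: np.ndarray | None = None,
    pool_width: int = 2276,
) -> np.ndarray:
    """Per-sample missing-call counts summing to ~fraction of the matrix.

    If an empirical per-sample pool is supplied it is resampled and rescaled
    to the matrix width; otherwise a right-skewed lognormal shape is used.
    Either way the counts are scaled so the overall missing fraction matches
    ``fraction``.
    """
    if counts_pool is not None:
        base = rng.choice(np.asarray(counts_pool, dtype=np.float64), size=n_samples)
        base *= n_sites / pool_width
    else:
        base = rng.lognormal(mean=0.0, sigma=0.9, size=n_samples)
    target_total = fraction * n_samples * n_sites
    base *= target_total / base.sum()
    counts = np.minimum(np.round(base).astype(np.int64), n_sites)
    counts = np.maximum(counts, 0)
    return counts


def draw_site_weights(
    n_sites: int, rng: np.random.Generator, sigma: float = SITE_CLUSTER_SIGMA
) -> np.ndarray:
    """Per-site masking weights (lognormal, heavy-tailed, normalized)."""
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n_sites)
    return w / w.sum()


def apply_missingness(
    m: HaplotypeMatrix,
    counts: np.ndarray,
    rng: np.random.Generator,
    site_weights: np.ndarray | None = None,
) -> HaplotypeMatrix:
    """Mask ``counts[i]`` calls in each sample row.

    With ``site_weights`` the masked positions are drawn (without
    replacement) proportionally to the weights, clustering missingness on
    shared hard-to-call sites; otherwise placement is uniform.
    """
    G = m.genotypes.copy()
    n, S = G.shape
    for i in range(n):
        k = int(counts[i])
        if k > 0:
            cols = rng.choice(S, size=k, replace=False, p=site_weights)
            G[i, cols] = MISSING
    return HaplotypeMatrix(
        sample_ids=list(m.sample_ids), sites=list(m.sites),
        genotypes=G, locus_label=m.locus_label,
    )


def mask_and_validate(
    m: HaplotypeMatrix,
    fraction: float = 0.0254,
    per_sample_counts: np.ndarray | None = None,
    reps: int = 10,
    seed: int = 0,
) -> MaskingReport:
    """Randomly delete known alleles, re-impute, and score accuracy.

    Per replicate the requested fraction of calls is masked, mirroring the
    missingness structure of real capture data: a right-skewed per-sample
    count distribution (optionally resampled from a supplied empirical
    vector) and site-clustered placement.  The matrix is re-imputed and
    accuracy is the fraction of imputed alleles equal to the truth.
    Deterministic given ``seed``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("masking fraction must be in (0, 1)")
    if (m.genotypes == MISSING).any():
        raise ValueError("mask_and_validate requires a complete matrix")
    rng = np.random.default_rng(seed)
    accuracies = np.empty(reps, dtype=np.float64)
    for r in range(reps):
        counts = draw_missing_counts(
            m.n_samples, m.n_sites, fraction, rng, counts_pool=per_sample_counts
        )
        weights = draw_site_weights(m.n_sites, rng)
        masked = apply_missingness(m, counts, rng, site_weights=weights)
        result = impute_missing(masked)
        cells = masked.genotypes == MISSING
        agree = result.matrix.genotypes[cells] == m.genotypes[cells]
        accuracies[r] = float(agree.mean()) if cells.any() else 1.0
    return MaskingReport(
        replicates=reps, masked_fraction=fraction, per_replicate_accuracy=accuracies
    )
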