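# unidem

Comparative demographic inference from the two uniparental loci: complete
mitochondrial DNA (mtDNA, maternal) and the non-recombining portion of the Y
chromosome (NRY, paternal). Because both loci are inherited without
recombination from one parent, contrasting their diversity exposes
sex-biased history — differences between female and male effective
population sizes (N_f vs N_m), sex-biased migration, and region-specific
processes — that autosomal data average away.

`unidem` is a toolkit for population geneticists working with matched
mtDNA/NRY resequencing panels (e.g. HGDP-style worldwide samples). It
covers the full path from called genotypes to demographic estimates:

- **Haplotype-matrix QC** — PHRED-scaled genotype-likelihood (PL) calling
  for haploid loci (a site is set to missing unless the best homozygote
  beats both the other homozygote and the heterozygote by ≥ 30 PHRED
  units), multi-allelic site removal, and a maximum-parsimony homoplasy
  filter that drops SNPs mutating more than twice with every change on a
  terminal branch (a sequencing-error signature on a non-recombining
  locus).
- **Imputation** — sequential nearest-haplotype copying that exploits
  complete linkage: complete sites form a reference set, remaining sites
  are imputed in order of increasing missingness from the
  minimum-Hamming-distance donor, and each completed site joins the
  reference. A mask-and-revalidate protocol measures accuracy.
- **Diversity and differentiation statistics** — haplotype diversity H,
  segregating sites S, mean pairwise differences (mpd) with Tajima SEs,
  nucleotide diversity π = mpd/L, Watterson's θ_S, Tajima's D, pairwise
  Φ_ST, hierarchical AMOVA with permutation tests, an mpd-ratio
  (mpd_NRY/mpd_mt) resampling null, Mantel tests against great-circle
  geographic distances.
- **Structured-coalescent simulation** — a fast haploid simulator for a
  six-region serial-founder world model (Africa at T1, out-of-Africa
  bottleneck at T2, then Oceania, Europe, Central/East Asia, America
  splitting at T3–T6; exponential growth within each region, no migration
  after divergence; infinite-sites mutation), cross-validated against
  msprime.
- **Two-stage ABC** — approximate Bayesian computation with MAD-standardized
  rejection and Beaumont-style log-scale local-linear regression: stage 1
  estimates the divergence times T1–T6 from combined mtDNA+NRY summary
  statistics; stage 2 fixes those times and estimates 13 female (mtDNA) or
  male (NRY) effective-size parameters per region, with
  pseudo-observed-dataset validation (R², bias, relative RMSE, 90%-interval
  coverage, factor-2).
- **Synthetic data** — a generator that emulates a 623-male, 51-population,
  7-region panel (511 samples in the six modelled regions after exclusions)
  with realistic site-clustered missingness (2.54% overall), so the entire
  pipeline is testable without any external download.

## Worked example

Generate a synthetic study and compare maternal and paternal diversity:

```python
from unidem import synthetic_data as sd, diversity_stats
from unidem.haplotype_io import (read_variant_table, read_sample_metadata,
                                 read_fasta_alignment, extract_biallelic_sites)
from unidem.imputation import impute_missing

paths = sd.generate_study(sd.StudyConfig(seed=1), "study/")
meta = read_sample_metadata(paths["metadata"])
nry = read_variant_table(paths["nry_vcf"])
print(f"NRY: {nry.n_samples} samples x {nry.n_sites} sites, "
      f"{100 * nry.missing_fraction():.2f}% missing")
result = impute_missing(nry)
print(f"imputed {len(result.fill_log)} calls")
mt, _ = extract_biallelic_sites(read_fasta_alignment(paths["mtdna_fasta"]))

t = meta.table
for region in ("Africa", "Europe", "America"):
    mask = (t["region"] == region) & ~t["population"].isin(
        ("Adygei", "Hazara", "Uygur"))
    idx = [i for i, s in enumerate(nry.sample_ids)
           if s in set(t.loc[mask, "sample_id"])]
    d_nry = diversity_stats(result.matrix.take_samples(idx), L=501_108)
    d_mt = diversity_stats(mt.take_samples(idx), L=16_569)
    print(f"{region:10s} n={d_nry.n:3d}  NRY mpd={d_nry.mpd:5.1f}"
          f"  mt mpd={d_mt.mpd:5.1f}  ratio={d_nry.mpd / d_mt.mpd:.2f}")
```

Output:

```
NRY: 623 samples x 1729 sites, 2.54% missing
imputed 27359 calls
Africa     n= 85  NRY mpd= 37.6  mt mpd= 39.3  ratio=0.96
Europe     n= 79  NRY mpd= 16.8  mt mpd= 13.1  ratio=1.28
America    n= 22  NRY mpd=  4.3  mt mpd=  7.8  ratio=0.55
```

The mpd ratio below one in Africa and the Americas means paternal-line
diversity is depressed relative to maternal-line diversity in those
regional samples — in the Americas dramatically so, consistent with fewer
effective male than female founders under the simulated history.

The same analysis runs from the shell:

```bash
unidem synth --out study/ --seed 1
unidem impute study/nry.vcf --out study/nry_imputed.vcf --validate --reps 5
unidem pipeline --config pipeline.yaml     # full report bundle
```

`unidem pipeline` writes a diversity table (per-region n, H, S, mpd ± SE,
π ± SE, mpd ratio with resampling p), an AMOVA report (worldwide with and
without the regional level, plus per-region), Mantel correlations of Φ_ST
with geography, and the two ABC stages' posterior tables (mean, mode, 95%
HPD per parameter, with optional pod-validation columns).

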