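"""Synthetic HGDP-like study generator.

Produces a complete, fully synthetic input set for the pipeline: mtDNA
sequences (FASTA), an NRY-like variant table with realistic missingness
(VCF), the complete truth matrix, sample metadata with populations, regions,
coordinates and exclusion flags, and the true demographic parameters.

The default configuration emulates the real panel's shape: 623 males in 51
populations over 7 regions; the 6 modelled regions contribute
85/146/162/79/17/22 = 511 samples after excluding the ME/NA populations and
the admixed Adygei/Hazara/Uygur.  The ME/NA region is simulated as a
seventh deme (sister to Europe at T4) and admixed populations are drawn
inside their host demes but flagged excluded, so exclusion logic and
whole-panel resampling are exercised end to end.  True parameter defaults
are the posterior point estimates this pipeline is designed to reproduce.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalsim as cs
from .haplotype_io import (
    Alignment,
    HaplotypeMatrix,
    SampleTable,
    write_fasta_alignment,
    write_sample_metadata,
    write_variant_table,
)
from .imputation import apply_missingness, draw_missing_counts, draw_site_weights

__all__ = ["StudyConfig", "generate_study", "worked_fixture", "POPULATIONS",
           "default_true_models", "MTDNA_REFERENCE_LENGTH"]

MTDNA_REFERENCE_LENGTH = cs.MTDNA_NONCODING[0] + cs.MTDNA_CODING[0]  # 16,569 bp

# population, region, n male samples, latitude, longitude, excluded
# (synthetic gazetteer shaped like the HGDP panel; counts per region sum to
# 85/146/162/79/17/22 core + 75 ME/NA + 37 admixed = 623)
POPULATIONS: list[tuple[str, str, int, float, float, bool]] = [
    ("BantuKenya", "Africa", 11, -3.0, 37.0, False),
    ("BantuSouthAfrica", "Africa", 8, -29.0, 29.0, False),
    ("Biaka", "Africa", 22, 4.0, 17.0, False),
    ("Mandenka", "Africa", 13, 12.0, -12.0, False),
    ("Mbuti", "Africa", 13, 1.0, 29.0, False),
    ("San", "Africa", 5, -21.0, 20.0, False),
    ("Yoruba", "Africa", 13, 8.0, 5.0, False),
    ("Melanesian", "Oceania", 9, -6.0, 155.0, False),
    ("Papuan", "Oceania", 8, -4.0, 143.0, False),
    ("Basque", "Europe", 12, 43.0, 0.0, False),
    ("French", "Europe", 14, 46.0, 2.0, False),
    ("Italian", "Europe", 8, 46.0, 10.0, False),
    ("Orcadian", "Europe", 8, 59.0, -3.0, False),
    ("Russian", "Europe", 13, 61.0, 40.0, False),
    ("Sardinian", "Europe", 14, 40.0, 9.0, False),
    ("Tuscan", "Europe", 10, 43.0, 11.0, False),
    ("Adygei", "Europe", 15, 44.0, 39.0, True),
    ("Balochi", "Central Asia", 21, 30.5, 66.5, False),
    ("Brahui", "Central Asia", 21, 30.0, 66.0, False),
    ("Burusho", "Central Asia", 20, 36.5, 74.0, False),
    ("Kalash", "Central Asia", 18, 35.5, 71.5, False),
    ("Makrani", "Central Asia", 22, 26.0, 64.0, False),
    ("Pathan", "Central Asia", 22, 33.5, 70.5, False),
    ("Sindhi", "Central Asia", 22, 25.5, 69.0, False),
    ("Hazara", "Central Asia", 12, 33.5, 70.0, True),
    ("Uygur", "Central Asia", 10, 44.0, 81.0, True),
    ("Cambodian", "East Asia", 8, 12.0, 105.0, False),
    ("Dai", "East Asia", 8, 21.0, 100.0, False),
    ("Daur", "East Asia", 6, 48.5, 124.0, False),
    ("Han", "East Asia", 32, 32.3, 114.0, False),
    ("Hezhen", "East Asia", 6, 47.5, 133.5, False),
    ("Japanese", "East Asia", 26, 38.0, 138.0, False),
    ("Lahu", "East Asia", 6, 22.0, 100.0, False),
    ("Miao", "East Asia", 6, 28.0, 109.0, False),
    ("Mongola", "East Asia", 6, 45.0, 111.0, False),
    ("Naxi", "East Asia", 6, 26.0, 100.0, False),
    ("Oroqen", "East Asia", 6, 50.4, 126.5, False),
    ("She", "East Asia", 6, 27.0, 119.0, False),
    ("Tu", "East Asia", 6, 36.0, 101.0, False),
    ("Tujia", "East Asia", 5, 29.0, 109.0, False),
    ("Xibo", "East Asia", 5, 43.5, 81.5, False),
    ("Yakut", "East Asia", 24, 63.0, 129.5, False),
    ("Colombian", "America", 4, 3.0, -68.0, False),
    ("Karitiana", "America", 6, -10.0, -63.0, False),
    ("Maya", "America", 5, 19.0, -91.0, False),
    ("Pima", "America", 4, 29.0, -108.0, False),
    ("Surui", "America", 3, -11.0, -62.0, False),
    ("Bedouin", "ME/NA", 21, 31.0, 35.0, False),
    ("Druze", "ME/NA", 20, 32.0, 35.0, False),
    ("Mozabite", "ME/NA", 20, 32.0, 3.0, False),
    ("Palestinian", "ME/NA", 14, 32.0, 35.0, False),
]


def default_true_models(generation_time: float = 25.0):
    """True (N_f, N_m) histories used by the generator by default.

    Divergence times are the combined-locus posterior means; the size values
    are the per-region posterior means of the female (mtDNA) and male (NRY)
    effective sizes that this pipeline is designed to recover.
    """
    times = dict(zip(cs.TIME_PARAM_NAMES, (107_067.0, 74_916.0, 63_210.0,
                                           49_280.0, 36_700.0, 15_828.0)))
    nry = cs.DemographicModel(
        **times,
        N_anc_africa=32.0,
        N_ooa=15.0,
        N_anc={"Oceania": 30.0, "Europe": 18.0, "Central Asia": 74.0,
               "East Asia": 4_935.0, "America": 21.0},
        N_cur={"Africa": 6_565.0, "Oceania": 2_060.0, "Europe": 3_815.0,
               "Central Asia": 8_579.0, "East Asia": 22_009.0, "America": 685.0},
        generation_time=generation_time,
    )
    mt = cs.DemographicModel(
        **times,
        N_anc_africa=57.0,
        N_ooa=26.0,
        N_anc={"Oceania": 52.0, "Europe": 118.0, "Central Asia": 1_663.0,
               "East Asia": 4_710.0, "America": 90.0},
        N_cur={"Africa": 11_505.0, "Oceania": 3_509.0, "Europe": 8_029.0,
               "Central Asia": 29_513.0, "East Asia": 100_111.0,
               "America": 1_802.0},
        generation_time=generation_time,
    )
    return {"mtDNA": mt, "NRY": nry}


@dataclasses.dataclass
class StudyConfig:
    populations: list[tuple[str, str, int, float, float, bool]] = dataclasses.field(
        default_factory=lambda: [tuple(p) for p in POPULATIONS]
    )
    true_models: dict | None = None          # {"mtDNA": model, "NRY": model}
    # ME/NA deme sizes (founding, current) for (mtDNA, NRY) runs
    mena_sizes_mt: tuple[float, float] = (120.0, 8_000.0)
    mena_sizes_nry: tuple[float, float] = (20.0, 4_000.0)
    missing_fraction: float = 0.0254
    nry_rate: str | float = "average"
    generation_time: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_models is None:
            self.true_models = default_true_models(self.generation_time)
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing fraction must be in [0, 1)")
        counts = {}
        for _, region, n, _, _, _ in self.populations:
            counts[region] = counts.get(region, 0) + n
        if any(p[2] <= 0 for p in self.populations):
            raise ValueError("population sample counts must be positive")
        self.region_counts = counts

    def sample_config(self) -> cs.SampleConfig:
        return cs.SampleConfig(counts=dict(self.region_counts))

    def metadata(self) -> SampleTable:
        """Sample rows ordered to match the simulator's leaf order."""
        rows = []
        idx = 1
        deme_order = list(cs.REGION_ORDER) + [cs.MENA]
        for region in deme_order:
            pops = [p for p in self.populations if p[1] == region]
            # non-excluded populations first within each deme
            pops.sort(key=lambda p: (p[5], p[0]))
            for name, reg, n, lat, lon, excl in pops:
                for k in range(n):
                    rows.append(
                        {
                            "sample_id": f"{name}{k + 1:02d}",
                            "sex": "M",
                            "population": name,
                            "region": reg,
                            "latitude": lat,
                            "longitude": lon,
                            "excluded_flag": excl,
                        }
                    )
                    idx += 1
        return SampleTable(pd.DataFrame(rows))


def _mtdna_reference() -> str:
    """Fixed arbitrary mtDNA-length reference sequence (deterministic)."""
    rng = np.random.default_rng(20140924)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, MTDNA_REFERENCE_LENGTH)])


def generate_study(cfg: StudyConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write a full synthetic study; deterministic given seed.

    Writes mtDNA FASTA (complete sequences), NRY VCF with missingness, the
    complete NRY truth VCF, metadata TSV and the true parameters JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = cfg.metadata()
    sample_ids = list(meta.table["sample_id"])
    sim_cfg = cfg.sample_config()
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(s) for k, s in zip(
        ("mt_tree", "mt_mut", "nry_tree", "nry_mut", "mask"),
        rng.integers(0, 2**31 - 2, size=5),
    )}

    # mtDNA: genealogy -> matrix -> full sequences
    mt_model = cfg.true_models["mtDNA"]
    mt_gen = cs.simulate_genealogy(
        mt_model, sim_cfg, seed=seeds["mt_tree"], mena_sizes=cfg.mena_sizes_mt
    )
    reference = _mtdna_reference()
    mt_matrix = cs.drop_mutations(
        mt_gen, cs.mtdna_locus(), seed=seeds["mt_mut"], ref_sequence=reference
    )
    mt_matrix.sample_ids = sample_ids
    mt_matrix.locus_label = "mtDNA"
    sequences = []
    ref_arr = np.array(list(reference))
    for i in range(len(sample_ids)):
        seq = ref_arr.copy()
        carried = np.flatnonzero(mt_matrix.genotypes[i] == 1)
        for j in carried:
            site = mt_matrix.sites[j]
            seq[site.position - 1] = site.alt_allele
        sequences.append("".join(seq))
    fasta_path = out / "mtdna.fasta"
    write_fasta_alignment(Alignment(sample_ids, sequences), fasta_path)

    # NRY: genealogy -> truth matrix -> masked matrix
    nry_model = cfg.true_models["NRY"]
    nry_gen = cs.simulate_genealogy(
        nry_model, sim_cfg, seed=seeds["nry_tree"], mena_sizes=cfg.mena_sizes_nry
    )
    nry_truth = cs.drop_mutations(
        nry_gen, cs.nry_locus(cfg.nry_rate), seed=seeds["nry_mut"]
    )
    nry_truth.sample_ids = sample_ids
    nry_truth.locus_label = "NRY"
    mask_rng = np.random.default_rng(seeds["mask"])
    if cfg.missing_fraction > 0:
        counts = draw_missing_counts(
            nry_truth.n_samples, nry_truth.n_sites, cfg.missing_fraction, mask_rng
        )
        weights = draw_site_weights(nry_truth.n_sites, mask_rng)
        nry_masked = apply_missingness(nry_truth, counts, mask_rng,
                                       site_weights=weights)
    else:
        nry_masked = nry_truth.copy()
    truth_path = out / "nry_truth.vcf"
    masked_path = out / "nry.vcf"
    write_variant_table(nry_truth, truth_path, format="vcf")
    write_variant_table(nry_masked, masked_path, format="vcf")

    meta_path = out / "metadata.tsv"
    write_sample_metadata(meta, meta_path)

    params_path = out / "truth_params.json"
    truth = {
        "times_years": dict(zip(cs.TIME_PARAM_NAMES,
                                map(float, mt_model.times_years))),
        "sizes": {
            label: dict(zip(cs.SIZE_PARAM_NAMES,
                            map(float, cs.size_params_of(model))))
            for label, model in (("mtDNA", mt_model), ("NRY", nry_model))
        },
        "generation_time": cfg.generation_time,
        "missing_fraction": cfg.missing_fraction,
        "seed": cfg.seed,
    }
    params_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {
        "mtdna_fasta": fasta_path,
        "nry_vcf": masked_path,
        "nry_truth_vcf": truth_path,
        "metadata": meta_path,
        "truth_params": params_path,
    }


# ---------------------------------------------------------------------------
# Hand-checkable worked fixtures
# ---------------------------------------------------------------------------

def worked_fixture() -> dict:
    """Tiny fixed datasets with hand-computed expected outputs.

    ``tajima4``: the 4-haplotype diversity example; ``impute3``: the
    three-haplotype nearest-donor imputation example; ``phist22``: the
    2+2-sample two-population Phi_ST example.  Stable across runs.
    """
    from .haplotype_io import Site

    def matrix(rows: list[str], label: str = "synthetic") -> HaplotypeMatrix:
        geno = np.array(
            [[-1 if ch == "N" else int(ch) for ch in row] for row in rows],
            dtype=np.int8,
        )
        return HaplotypeMatrix(
            sample_ids=[f"h{i + 1}" for i in range(len(rows))],
            sites=[Site(j + 1, "A", "G") for j in range(geno.shape[1])],
            genotypes=geno,
            locus_label=label,
        )

    return {
        "tajima4": {
            "matrix": matrix(["000", "001", "011", "111"]),
            "L": 6,
            "expected": {
                "S": 3,
                "mpd": 10.0 / 6.0,
                "pi": 10.0 / 36.0,
                "H": 1.0,
                "theta_S": 18.0 / 11.0,
                "tajimas_D": 0.1676557950339493,
            },
        },
        "impute3": {
            "matrix": matrix(["0000", "1101", "111N"]),
            "expected": {"sample": "h3", "position": 4, "allele": 1},
        },
        "phist22": {
            "matrix": matrix(["000", "001", "110", "111"]),
            "populations": ["p1", "p1", "p2", "p2"],
            "expected": {"sigma_a": 0.75, "sigma_c": 0.5, "phi_st": 0.6},
        },
    }
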