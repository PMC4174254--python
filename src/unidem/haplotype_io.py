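"""Reading/writing alignments, variant tables and sample metadata.

The central in-memory substrate is :class:`HaplotypeMatrix`: samples x
biallelic sites with codes 0 (reference allele), 1 (alternative allele) and
N (missing; stored internally as -1 in an int8 array).  Positions are
1-based in files (VCF convention) and kept 1-based on the ``Site`` records;
column indices are the usual 0-based numpy indices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = np.int8(-1)

#: Fixed regional vocabulary (HGDP-style groupings).
REGIONS = (
    "Africa",
    "America",
    "Central Asia",
    "East Asia",
    "Europe",
    "ME/NA",
    "Oceania",
)

VALID_BASES = frozenset("ACGT")


class AlignmentShapeError(ValueError):
    """Sequences in an alignment do not all have the same length."""


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Alignment:
    """A multiple sequence alignment of equal-length haploid sequences."""

    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("sample_ids and sequences length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment; sequences are upper-cased, order preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(
        sample_ids=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
    )


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# HaplotypeMatrix
# ---------------------------------------------------------------------------

class Site(NamedTuple):
    position: int  # 1-based coordinate
    ref_allele: str
    alt_allele: str


@dataclasses.dataclass
class HaplotypeMatrix:
    """Samples x biallelic sites with {0, 1, N} codes (N stored as -1)."""

    sample_ids: list[str]
    sites: list[Site]
    genotypes: np.ndarray  # int8, shape (n_samples, n_sites)
    locus_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, s = self.genotypes.shape if self.genotypes.ndim == 2 else (0, 0)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        if n != len(self.sample_ids) or s != len(self.sites):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        positions = [site.position for site in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("site positions must be strictly increasing")
        bad = ~np.isin(self.genotypes, (-1, 0, 1))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, -1 (N)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)

    @property
    def n_missing(self) -> int:
        return int((self.genotypes == MISSING).sum())

    def missing_fraction(self) -> float:
        return self.n_missing / self.genotypes.size if self.genotypes.size else 0.0

    def copy(self) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=list(self.sites),
            genotypes=self.genotypes.copy(),
            locus_label=self.locus_label,
        )

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return HaplotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=[self.sites[i] for i in index],
            genotypes=self.genotypes[:, index],
            locus_label=self.locus_label,
        )

    def take_samples(self, index: Sequence[int]) -> "HaplotypeMatrix":
        index = list(index)
        return HaplotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            sites=list(self.sites),
            genotypes=self.genotypes[index, :],
            locus_label=self.locus_label,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.sites == other.sites
            and np.array_equal(self.genotypes, other.genotypes)
        )


def extract_biallelic_sites(aln: Alignment) -> tuple[HaplotypeMatrix, dict]:
    """Collapse an alignment to the biallelic variable columns.

    '-', 'N' and IUPAC ambiguity codes are all treated as missing.  Invariant
    columns and columns with more than two distinct non-missing bases are
    dropped.  At each kept column the majority base becomes the reference
    (code 0); ties are broken toward the alphabetically smaller base.
    """
    if aln.n_samples == 0:
        raise FormatError("empty alignment")
    arr = np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype="S1"
    ).reshape(aln.n_samples, aln.length)
    sites: list[Site] = []
    columns: list[np.ndarray] = []
    n_invariant = 0
    n_multiallelic = 0
    for j in range(aln.length):
        col = arr[:, j]
        bases = {}
        for b in col:
            ch = b.decode()
            if ch in VALID_BASES:
                bases[ch] = bases.get(ch, 0) + 1
        if len(bases) <= 1:
            n_invariant += 1
            continue
        if len(bases) > 2:
            n_multiallelic += 1
            continue
        # majority base = ref; alphabetical tie-break
        (b1, c1), (b2, c2) = sorted(bases.items())
        ref, alt = (b1, b2) if c1 >= c2 else (b2, b1)
        codes = np.full(aln.n_samples, MISSING, dtype=np.int8)
        codes[col == ref.encode()] = 0
        codes[col == alt.encode()] = 1
        sites.append(Site(position=j + 1, ref_allele=ref, alt_allele=alt))
        columns.append(codes)
    genotypes = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((aln.n_samples, 0), dtype=np.int8)
    )
    matrix = HaplotypeMatrix(
        sample_ids=list(aln.sample_ids),
        sites=sites,
        genotypes=genotypes,
        locus_label="mtDNA",
    )
    report = {
        "n_invariant_dropped": n_invariant,
        "n_multiallelic_dropped": n_multiallelic,
        "n_sites_kept": len(sites),
    }
    return matrix, report


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "sample_id",
    "sex",
    "population",
    "region",
    "latitude",
    "longitude",
    "excluded_flag",
]


@dataclasses.dataclass
class SampleTable:
    """sample -> population -> region metadata with coordinates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing_cols:
            raise FormatError(f"metadata missing columns: {missing_cols}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample_id: {sorted(set(dups))}")
        unknown = set(self.table["region"]) - set(REGIONS)
        if unknown:
            raise FormatError(f"unknown region(s): {sorted(unknown)}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def region_of(self, sample_ids: Iterable[str]) -> list[str]:
        lookup = dict(zip(self.table["sample_id"], self.table["region"]))
        return [lookup[s] for s in sample_ids]

    def population_of(self, sample_ids: Iterable[str]) -> list[str]:
        lookup = dict(zip(self.table["sample_id"], self.table["population"]))
        return [lookup[s] for s in sample_ids]

    def included(self) -> "SampleTable":
        """Rows not flagged as excluded (admixed / ME-NA samples)."""
        return SampleTable(self.table[~self.table["excluded_flag"]].copy())

    def has_coordinates(self) -> pd.Series:
        return self.table["latitude"].notna() & self.table["longitude"].notna()


def read_sample_metadata(path: str | Path) -> SampleTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "sex": str, "population": str, "region": str},
    )
    df["latitude"] = pd.to_numeric(df.get("latitude"), errors="coerce")
    df["longitude"] = pd.to_numeric(df.get("longitude"), errors="coerce")
    if "excluded_flag" in df.columns:
        df["excluded_flag"] = (
            df["excluded_flag"]
            .astype(str)
            .str.lower()
            .isin(("1", "true", "yes"))
        )
    return SampleTable(df)


def write_sample_metadata(table: SampleTable, path: str | Path) -> None:
    out = table.table.copy()
    out["excluded_flag"] = out["excluded_flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PL-based genotype calling
# ---------------------------------------------------------------------------

class PLRecord(NamedTuple):
    position: int
    sample_id: str
    pl: tuple[float, float, float]  # PHRED likelihoods for (0/0, 0/1, 1/1)


def call_genotypes_from_pl(
    records: Iterable[PLRecord],
    min_diff: float = 30.0,
    alleles: dict[int, tuple[str, str]] | None = None,
    locus_label: str = "NRY",
) -> HaplotypeMatrix:
    """Call haploid genotypes from PHRED-scaled genotype-likelihood triples.

    A site/sample is called N when (a) the two homozygote PLs differ by less
    than ``min_diff``, (b) the heterozygote PL is lower than the best
    homozygote PL, or (c) the heterozygote PL is within ``min_diff`` of the
    best homozygote PL; otherwise the allele of the lower homozygote PL is
    called.
    """
    records = list(records)
    positions = sorted({r.position for r in records})
    samples = sorted({r.sample_id for r in records})
    pos_index = {p: i for i, p in enumerate(positions)}
    sample_index = {s: i for i, s in enumerate(samples)}
    seen = np.zeros((len(samples), len(positions)), dtype=bool)
    genotypes = np.full((len(samples), len(positions)), MISSING, dtype=np.int8)
    for rec in records:
        pl00, pl01, pl11 = rec.pl
        if min(rec.pl) < 0:
            raise ValueError(f"negative PL score in {rec}")
        i, j = sample_index[rec.sample_id], pos_index[rec.position]
        if seen[i, j]:
            raise FormatError(f"duplicate PL record for {rec.sample_id}@{rec.position}")
        seen[i, j] = True
        best_hom = min(pl00, pl11)
        if abs(pl11 - pl00) < min_diff:
            call = MISSING
        elif pl01 < best_hom or (pl01 - best_hom) < min_diff:
            call = MISSING
        else:
            call = np.int8(0) if pl00 < pl11 else np.int8(1)
        genotypes[i, j] = call
    if not seen.all():
        raise ValueError("every (site, sample) pair needs exactly one PLRecord")
    alleles = alleles or {}
    sites = [Site(p, *alleles.get(p, ("A", "G"))) for p in positions]
    return HaplotypeMatrix(
        sample_ids=samples, sites=sites, genotypes=genotypes, locus_label=locus_label
    )


# ---------------------------------------------------------------------------
# Variant tables (haploid VCF dialect / TSV)
# ---------------------------------------------------------------------------

_CONTIG = {"mtDNA": "chrM", "NRY": "chrY", "synthetic": "chrS"}


def write_variant_table(
    m: HaplotypeMatrix, path: str | Path, format: str = "vcf"
) -> None:
    """Write a matrix as a haploid VCF (GT in {0, 1, .}) or a wide TSV."""
    if format == "vcf":
        _write_vcf(m, path)
    elif format == "tsv":
        _write_tsv(m, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_variant_table(path: str | Path, format: str | None = None) -> HaplotypeMatrix:
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _write_vcf(m: HaplotypeMatrix, path: str | Path) -> None:
    contig = _CONTIG.get(m.locus_label, "chrS")
    header = pysam.VariantHeader()
    header.add_line(f"##unidemLocus={m.locus_label}")
    max_pos = int(m.positions.max()) if m.n_sites else 1
    header.contigs.add(contig, length=max(max_pos + 1, 2))
    header.formats.add("GT", 1, "String", "Haploid genotype")
    for sid in m.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, site in enumerate(m.sites):
            rec = vcf.new_record(
                contig=contig,
                start=site.position - 1,
                stop=site.position,
                alleles=(site.ref_allele, site.alt_allele),
            )
            for i, sid in enumerate(m.sample_ids):
                g = int(m.genotypes[i, j])
                rec.samples[sid]["GT"] = (None,) if g == MISSING else (g,)
            vcf.write(rec)


def _read_vcf(path: str | Path) -> HaplotypeMatrix:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        locus_label = "synthetic"
        for line in str(vcf.header).splitlines():
            if line.startswith("##unidemLocus="):
                locus_label = line.split("=", 1)[1]
        sites: list[Site] = []
        cols: list[np.ndarray] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(f"expected exactly one ALT at {rec.pos}")
            sites.append(Site(rec.pos, rec.ref, rec.alts[0]))
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, sid in enumerate(samples):
                gt = rec.samples[sid]["GT"]
                if gt and gt[0] is not None:
                    col[i] = gt[0]
            cols.append(col)
    genotypes = (
        np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return HaplotypeMatrix(
        sample_ids=samples, sites=sites, genotypes=genotypes, locus_label=locus_label
    )


def _write_tsv(m: HaplotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "position": [s.position for s in m.sites],
            "ref": [s.ref_allele for s in m.sites],
            "alt": [s.alt_allele for s in m.sites],
        }
    )
    geno = pd.DataFrame(
        m.genotypes.T, columns=m.sample_ids
    ).replace(-1, "N")
    df = pd.concat([df, geno], axis=1)
    with open(path, "w") as fh:
        fh.write(f"#locus={m.locus_label}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path) -> HaplotypeMatrix:
    locus_label = "synthetic"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#locus="):
            locus_label = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    sample_ids = [c for c in df.columns if c not in ("position", "ref", "alt")]
    sites = [
        Site(int(p), r, a) for p, r, a in zip(df["position"], df["ref"], df["alt"])
    ]
    geno = (
        df[sample_ids]
        .replace("N", -1)
        .astype(np.int8)
        .to_numpy()
        .T
    )
    if geno.size == 0:
        geno = np.zeros((len(sample_ids), 0), dtype=np.int8)
    return HaplotypeMatrix(
        sample_ids=sample_ids, sites=sites, genotypes=geno, locus_label=locus_label
    )
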