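"""Readers and writers for the external text formats the pipeline consumes.

Formats
-------
* ``sync`` — the standard pool-seq count format (one line per site:
  chromosome, 1-based position, reference base, then one colon-separated
  ``A:T:C:G:N:del`` count tuple per pool).
* FASTA haplotype alignments (equal-length, alphabet ``ACGTN-``).
* Genotype tables — one row per individual (id, population, phenotype,
  then per-SNP dosage codes 0/1/2 or a missing token), with an optional
  companion per-SNP QC table (GC50, GenTrain, call rate).
* A minimal VCF 4.2 writer for scan results.

All coordinates are 1-based inclusive.  N and deletion slots of sync tuples
are parsed and round-tripped but excluded from allele-frequency work
downstream (reads with ambiguous bases are not trusted as allele evidence).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity_neutrality import HaplotypeAlignment

__all__ = [
    "SyncRecord",
    "RunConfig",
    "GenotypeMatrix",
    "read_sync",
    "write_sync",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_genotype_table",
    "write_genotype_table",
    "write_vcf",
]

#: order of the count slots in a sync tuple
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: slots that count as real allele evidence
NUCLEOTIDES = ("A", "T", "C", "G")


@dataclass(frozen=True)
class SyncRecord:
    """Per-site allele read counts for each pool."""

    chrom: str
    pos: int
    ref: str
    pool_counts: tuple  # one 6-tuple (A,T,C,G,N,del) per pool

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.pool_counts:
            raise ValueError("at least one pool of counts required")
        for counts in self.pool_counts:
            if len(counts) != 6:
                raise ValueError(
                    f"each pool needs exactly 6 counts (A:T:C:G:N:del), "
                    f"got {len(counts)}"
                )
            if any(c < 0 for c in counts):
                raise ValueError("counts must be non-negative")

    @property
    def n_pools(self) -> int:
        return len(self.pool_counts)

    def nucleotide_counts(self, pool: int) -> dict:
        """A/T/C/G counts for one pool (N and deletions excluded)."""
        return dict(zip(NUCLEOTIDES, self.pool_counts[pool][:4]))


@dataclass
class RunConfig:
    """Thresholds and bookkeeping shared across the pipeline.

    Defaults encode the scan's calling rules: sites need read coverage of at
    least 10 in each pool, the minor allele must be seen on at least two
    reads, and its overall frequency must reach 1%; outliers sit in the upper
    1% tail of the Fst distribution with q-value below 0.005.
    """

    seed: int = 0
    min_coverage: int = 10
    min_supporting_reads: int = 2
    min_maf: float = 0.01
    fst_tail_fraction: float = 0.01
    q_max: float = 0.005
    n_permutations: int = 1000
    n_coalescent_reps: int = 1000
    out_dir: str = "results"

    def __post_init__(self):
        for name in ("min_maf", "fst_tail_fraction", "q_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_coverage < 1 or self.min_supporting_reads < 1:
            raise ValueError("coverage thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def audit_header(self, version: str = "0.1.0") -> str:
        """Comment block stamped on every output file."""
        fields = dataclasses.asdict(self)
        parts = [f"{k}={v}" for k, v in fields.items()]
        return f"# btiscan v{version} | " + " ".join(parts)


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def read_sync(path) -> List[SyncRecord]:
    """Parse a sync file into records, validating every line.

    Raises ValueError naming the offending line for malformed tuples and for
    lines whose pool count differs from the first line.
    """
    records: List[SyncRecord] = []
    n_pools = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected chrom, pos, ref and at least "
                    f"one count tuple, got {len(fields)} fields"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: position {pos_s!r} not an integer")
            pools = []
            for tup in fields[3:]:
                parts = tup.split(":")
                if len(parts) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: count tuple {tup!r} has "
                        f"{len(parts)} fields, expected 6 (A:T:C:G:N:del)"
                    )
                try:
                    counts = tuple(int(p) for p in parts)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer count in {tup!r}")
                pools.append(counts)
            if n_pools is None:
                n_pools = len(pools)
            elif len(pools) != n_pools:
                raise ValueError(
                    f"{path}:{lineno}: {len(pools)} pools, expected {n_pools}"
                )
            try:
                records.append(
                    SyncRecord(chrom=chrom, pos=pos, ref=ref, pool_counts=tuple(pools))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_sync(records: Iterable[SyncRecord], path, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for rec in records:
            pools = "\t".join(
                ":".join(str(c) for c in counts) for counts in rec.pool_counts
            )
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{pools}\n")


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta_alignment(path, label: str = "") -> HaplotypeAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    names = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    # HaplotypeAlignment validates equal lengths and the alphabet
    return HaplotypeAlignment(names=names, sequences=seqs, label=label or Path(path).stem)


def write_fasta_alignment(aln: HaplotypeAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(aln.names, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals × SNPs dosage matrix with missing mask and metadata.

    ``genotypes`` is a float array with NaN for missing calls; dosages count
    copies of the SNP's counted allele (0, 1 or 2).  ``phenotypes`` carries
    each individual's assigned phenotype (e.g. its population's LC95).
    """

    individuals: list
    populations: list
    phenotypes: np.ndarray
    snp_names: list
    genotypes: np.ndarray  # floats with NaN = missing
    qc: Optional[pd.DataFrame] = None  # per-SNP: gc50, gentrain, cr

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        n, m = self.genotypes.shape
        if len(self.individuals) != n or len(self.populations) != n:
            raise ValueError("individual metadata does not match genotype rows")
        if len(self.snp_names) != m:
            raise ValueError("snp_names does not match genotype columns")
        if len(set(self.snp_names)) != m:
            raise ValueError("duplicated SNP names")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals) - {0.0, 1.0, 2.0})
            raise ValueError(f"genotype codes outside {{0,1,2,NA}}: {bad}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.genotypes)

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return self.missing_mask.mean(axis=0)


def read_genotype_table(path, qc_path=None, na_token: str = "NA") -> GenotypeMatrix:
    """Read a tabular genotype file.

    Expected columns: ``individual``, ``population``, ``phenotype``, then one
    column per SNP holding 0/1/2 or the missing token.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["individual", "population", "phenotype"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    snp_names = [c for c in df.columns if c not in required]
    if not snp_names:
        raise ValueError(f"{path}: no SNP columns found")
    geno = np.full((len(df), len(snp_names)), np.nan)
    for j, snp in enumerate(snp_names):
        col = df[snp].astype(str).str.strip()
        is_na = (col == na_token) | (col == "") | (col.str.lower() == "nan")
        vals = col.where(~is_na, other="0")
        try:
            numeric = vals.astype(float)
        except ValueError:
            raise ValueError(f"{path}: non-numeric genotype code in SNP {snp!r}")
        bad = ~np.isin(numeric, (0.0, 1.0, 2.0)) & ~is_na.to_numpy()
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"{path}: genotype code {col.iloc[i]!r} outside {{0,1,2,{na_token}}} "
                f"at individual {df['individual'].iloc[i]!r}, SNP {snp!r}"
            )
        geno[:, j] = np.where(is_na, np.nan, numeric)
    qc = None
    if qc_path is not None:
        qc = pd.read_csv(qc_path, sep="\t", comment="#").set_index("snp")
    return GenotypeMatrix(
        individuals=df["individual"].tolist(),
        populations=df["population"].tolist(),
        phenotypes=df["phenotype"].astype(float).to_numpy(),
        snp_names=snp_names,
        genotypes=geno,
        qc=qc,
    )


def write_genotype_table(gm: GenotypeMatrix, path, qc_path=None,
                         na_token: str = "NA", header: Optional[str] = None) -> None:
    cols = {
        "individual": gm.individuals,
        "population": gm.populations,
        "phenotype": gm.phenotypes,
    }
    for j, snp in enumerate(gm.snp_names):
        col = gm.genotypes[:, j]
        cols[snp] = [na_token if np.isnan(v) else str(int(v)) for v in col]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)
    if qc_path is not None and gm.qc is not None:
        gm.qc.reset_index().to_csv(qc_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=FST,Number=1,Type=Float,Description="Pairwise pool Fst">
##INFO=<ID=FISHER_P,Number=1,Type=Float,Description="Two-sided Fisher exact p for allele-frequency difference">
##INFO=<ID=QVAL,Number=1,Type=Float,Description="Storey q-value">
##INFO=<ID=OUTLIER,Number=0,Type=Flag,Description="Empirical Fst-tail and q-value outlier">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Minor-allele frequency in the pool">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read coverage in the pool">
"""


def write_vcf(snps, path, sample_names=("POOL1", "POOL2"),
              audit: Optional[str] = None) -> None:
    """Write scan results as a minimal VCF 4.2 file.

    ``snps`` are SnpRecord objects from the pooled scan, sorted by
    (chrom, pos); unsorted input is rejected.
    """
    keys = [(s.chrom, s.pos) for s in snps]
    if keys != sorted(keys):
        raise ValueError("SNPs must be sorted by (chrom, pos) for VCF output")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if audit:
            fh.write(f"##btiscan_audit={audit.lstrip('# ')}\n")
        for chrom in dict.fromkeys(s.chrom for s in snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for s in snps:
            info = f"FST={s.fst:.6g};FISHER_P={s.fisher_p:.6g};QVAL={s.qvalue:.6g}"
            if s.outlier:
                info += ";OUTLIER"
            samples = "\t".join(
                f"{s.pool_freqs[i]:.6g}:{s.pool_coverages[i]}"
                for i in range(len(sample_names))
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.chrom}_{s.pos}\t{s.major_allele}\t"
                f"{s.minor_allele}\t.\tPASS\t{info}\tAF:DP\t{samples}\n"
            )
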