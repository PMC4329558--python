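"""Readers and writers for genotype, covariate, gene and gene-set files.

Supported genotype formats:

* binary PLINK (``.bed``/``.bim``/``.fam`` triplet, SNP-major ``.bed`` with
  2-bit codes ``00`` hom A1 / ``10`` het / ``11`` hom A2 / ``01`` missing);
* a plain-text dialect (tab-separated samples x SNPs dosage table with an
  optional SNP metadata sidecar) for human-readable fixtures.

After loading, every dosage column is oriented to count the MINOR allele,
with allele frequency computed on cases and controls combined. Coordinates
are 1-based inclusive (PLINK .bim convention).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (
    CASE,
    CONTROL,
    GeneModel,
    GenotypeDataset,
    PathwayModel,
    SampleMeta,
    SnpMeta,
    orient_to_minor,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> count of the A1 allele (nan = missing)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])
# A1-allele count -> 2-bit code
_BED_ENCODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_MISSING_CODE = 0b01

_SEX_FROM_FAM = {"1": "male", "2": "female"}
_SEX_TO_FAM = {"male": "1", "female": "2"}
_STATUS_FROM_PLINK = {"1": CONTROL, "2": CASE}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class MatchReport:
    """Outcome of matching a covariate table against genotyped samples."""

    matched: list[str]
    genotyped_only: list[str]
    covariates_only: list[str]


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Load a PLINK bed/bim/fam triplet as a minor-allele dosage dataset.

    The ``.bed`` payload is decoded to counts of the A1 allele, then every
    column is re-oriented so dosages count the minor allele (frequency
    computed on all samples combined); allele labels in the returned
    :class:`SnpMeta` follow the re-orientation. Missing calls stay missing.
    """
    samples = _read_fam(fam_path)
    snp_rows = _read_bim(bim_path)
    n, m = len(samples), len(snp_rows)

    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes; not a SNP-major .bed file")
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    bytes_per_snp = (n + 3) // 4
    if payload.size != bytes_per_snp * m:
        raise FormatError(
            f"{bed_path}: payload is {payload.size} bytes but "
            f"{m} SNPs x {n} samples requires {bytes_per_snp * m}"
        )
    blocks = payload.reshape(m, bytes_per_snp)
    # unpack 4 samples per byte, low bits first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages_a1 = _BED_DECODE[codes[:, :n]].T  # samples x snps

    oriented, flipped = orient_to_minor(dosages_a1)
    snps = []
    for j, (snp_id, chrom, pos, a1, a2) in enumerate(snp_rows):
        minor, major = (a2, a1) if flipped[j] else (a1, a2)
        snps.append(SnpMeta(snp_id, chrom, pos, minor, major))
    return GenotypeDataset(oriented, samples, snps)


def write_plink(dataset: GenotypeDataset, prefix) -> None:
    """Write ``<prefix>.bed/.bim/.fam`` with A1 = the stored minor allele."""
    prefix = Path(prefix)
    n = dataset.n_samples

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in dataset.samples:
            sex = _SEX_TO_FAM.get(s.sex, "0")
            pheno = "2" if s.is_case else "1"
            fh.write(f"{s.sample_id} {s.sample_id} 0 0 {sex} {pheno}\n")

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in dataset.snps:
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}"
                f"\t{s.allele_minor}\t{s.allele_major}\n"
            )

    bytes_per_snp = (n + 3) // 4
    out = bytearray(_BED_MAGIC)
    for j in range(dataset.n_snps):
        col = dataset.dosages[:, j]
        block = bytearray(bytes_per_snp)
        for i in range(n):
            v = col[i]
            code = _MISSING_CODE if np.isnan(v) else _BED_ENCODE[v]
            block[i // 4] |= code << (2 * (i % 4))
        out += block
    prefix.with_suffix(".bed").write_bytes(bytes(out))


def _read_fam(fam_path) -> list[SampleMeta]:
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    samples = []
    for row in fam.itertuples(index=False):
        status = _STATUS_FROM_PLINK.get(row.phenotype, CONTROL)
        samples.append(
            SampleMeta(
                sample_id=row.iid,
                status=status,
                sex=_SEX_FROM_FAM.get(row.sex, "unknown"),
            )
        )
    return samples


def _read_bim(bim_path) -> list[tuple[str, str, int, str, str]]:
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    return [
        (r.snp_id, r.chrom, int(r.pos), r.a1, r.a2)
        for r in bim.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Plain-text dialect
# ---------------------------------------------------------------------------

def read_text_genotypes(geno_path, snp_table_path=None) -> GenotypeDataset:
    """Read the tab-separated samples x SNPs dosage dialect.

    The genotype table has a ``sample_id`` first column plus an optional
    ``status`` column; remaining columns are SNP ids with values 0/1/2 or
    ``NA``. ``snp_table_path`` optionally supplies SNP coordinates and
    alleles (columns: snp_id, chromosome, position, allele_minor,
    allele_major); without it SNPs are placed consecutively on chromosome 1
    with placeholder alleles.
    """
    tab = pd.read_csv(geno_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in tab.columns:
        raise FormatError(f"{geno_path}: missing sample_id column")
    status_col = tab.pop("status") if "status" in tab.columns else None
    sample_ids = tab.pop("sample_id").tolist()
    dosages = tab.to_numpy(dtype=float)
    oriented, flipped = orient_to_minor(dosages)

    if snp_table_path is not None:
        meta = pd.read_csv(snp_table_path, sep="\t", dtype=str).set_index("snp_id")
        snps = []
        for j, sid in enumerate(tab.columns):
            r = meta.loc[sid]
            minor, major = r["allele_minor"], r["allele_major"]
            if flipped[j]:
                minor, major = major, minor
            snps.append(SnpMeta(sid, r["chromosome"], int(r["position"]), minor, major))
    else:
        snps = [
            SnpMeta(sid, "1", j + 1, "B" if flipped[j] else "A",
                    "A" if flipped[j] else "B")
            for j, sid in enumerate(tab.columns)
        ]

    samples = []
    for i, sid in enumerate(sample_ids):
        status = CONTROL
        if status_col is not None:
            status = _parse_status(status_col.iloc[i])
        samples.append(SampleMeta(sample_id=sid, status=status))
    return GenotypeDataset(oriented, samples, snps)


def write_text_genotypes(dataset: GenotypeDataset, geno_path, snp_table_path=None) -> None:
    frame = pd.DataFrame(dataset.dosages, columns=dataset.snp_ids)
    frame.insert(0, "status", [s.status for s in dataset.samples])
    frame.insert(0, "sample_id", dataset.sample_ids)
    frame.to_csv(geno_path, sep="\t", index=False, na_rep="NA",
                 float_format="%.0f")
    if snp_table_path is not None:
        pd.DataFrame(
            {
                "snp_id": dataset.snp_ids,
                "chromosome": [s.chromosome for s in dataset.snps],
                "position": [s.position for s in dataset.snps],
                "allele_minor": [s.allele_minor for s in dataset.snps],
                "allele_major": [s.allele_major for s in dataset.snps],
            }
        ).to_csv(snp_table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Covariate table
# ---------------------------------------------------------------------------

def read_covariates(table_path) -> list[SampleMeta]:
    """Read the tab-separated sample covariate table.

    Required columns: ``sample_id`` and ``status`` (``case``/``control`` or
    the PLINK 2/1 convention). Optional: ``study``, ``sex``, ``age_stratum``;
    any additional numeric column becomes a named extra covariate.
    """
    tab = pd.read_csv(table_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "status"):
        if col not in tab.columns:
            raise FormatError(f"{table_path}: missing required column {col!r}")
    if tab["sample_id"].duplicated().any():
        dupes = tab["sample_id"][tab["sample_id"].duplicated()].tolist()
        raise FormatError(f"{table_path}: duplicated sample_id values: {dupes}")

    known = {"sample_id", "status", "study", "sex", "age_stratum"}
    extra_cols = [c for c in tab.columns if c not in known]
    samples = []
    for row in tab.itertuples(index=False):
        d = row._asdict()
        extras = {c: float(d[c]) for c in extra_cols if pd.notna(d[c])}
        samples.append(
            SampleMeta(
                sample_id=d["sample_id"],
                status=_parse_status(d["status"]),
                study=str(d.get("study", "study1")),
                sex=str(d.get("sex", "unknown")),
                age_stratum=str(d.get("age_stratum", "all")),
                extra_covariates=extras,
            )
        )
    return samples


def attach_covariates(
    dataset: GenotypeDataset, covariates: Sequence[SampleMeta]
) -> tuple[GenotypeDataset, MatchReport]:
    """Join covariate records onto a dataset by sample id.

    Samples without a covariate record are dropped from the returned dataset
    and listed in the report, as are covariate rows with no genotypes.
    """
    cov_by_id = {c.sample_id: c for c in covariates}
    geno_ids = dataset.sample_ids
    matched = [sid for sid in geno_ids if sid in cov_by_id]
    report = MatchReport(
        matched=matched,
        genotyped_only=[sid for sid in geno_ids if sid not in cov_by_id],
        covariates_only=sorted(set(cov_by_id) - set(geno_ids)),
    )
    sub = dataset.subset_samples(np.array([sid in cov_by_id for sid in geno_ids]))
    sub.samples = [cov_by_id[sid] for sid in sub.sample_ids]
    return sub, report


def _parse_status(value) -> str:
    s = str(value).strip().lower()
    if s in ("case", "2"):
        return CASE
    if s in ("control", "1", "0"):
        return CONTROL
    raise FormatError(f"unrecognised case/control status {value!r}")


# ---------------------------------------------------------------------------
# Gene table and GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_table(path) -> list[GeneModel]:
    """Read the tab-separated gene table: name, chromosome, strand, start, end."""
    tab = pd.read_csv(
        path, sep="\t",
        names=["gene_name", "chromosome", "strand", "start", "end"],
        dtype={"gene_name": str, "chromosome": str, "strand": str},
        comment="#", header=None, skiprows=_header_rows(path),
    )
    genes = []
    for row in tab.itertuples(index=False):
        try:
            genes.append(
                GeneModel(row.gene_name, row.chromosome, row.strand,
                          int(row.start), int(row.end))
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return genes


def _header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    if len(fields) >= 5:
        try:
            int(fields[3])
            return 0
        except ValueError:
            return 1
    return 1 if fields and fields[0].lower() in ("gene", "gene_name", "name") else 0


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_name\tchromosome\tstrand\tstart\tend\n")
        for g in genes:
            fh.write(f"{g.gene_name}\t{g.chromosome}\t{g.strand}\t{g.start}\t{g.end}\n")


def read_gmt(path) -> list[PathwayModel]:
    """Read a GMT gene-set file: name <tab> description <tab> gene...)"""
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            try:
                pathways.append(PathwayModel(name, tuple(genes)))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return pathways


def write_gmt(pathways: Sequence[PathwayModel], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_name, description, *p.genes]) + "\n")


def resolve_pathway_genes(
    pathway: PathwayModel, genes: Sequence[GeneModel]
) -> tuple[list[str], list[str]]:
    """Split a pathway's genes into (resolved, missing) against a gene table."""
    known = {g.gene_name for g in genes}
    resolved = [g for g in pathway.genes if g in known]
    missing = [g for g in pathway.genes if g not in known]
    return resolved, missing
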