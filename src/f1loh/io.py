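"""Readers and writers for the formats the pipeline touches.

Supported formats: minimal VCF 4.2 with per-sample AD/DP (via cyvcf2), TSV
mirrors of every table, a BED-like annotated segment file, JSON truth and
YAML configs.  Readers validate into the domain records of
:mod:`f1loh.types`; writers round-trip losslessly.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .types import DepthBin, Segment, SnpObservation, SomaticVariantRecord

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: a somatic call whose normal-sample alt fraction exceeds this bound is
#: flagged as likely germline contamination (never silently dropped).
GERMLINE_VAF_BOUND = 0.05

SNP_COLUMNS = ["chrom", "pos", "b6_allele", "s129_allele",
               "normal_ref", "normal_alt", "tumor_ref", "tumor_alt"]
VARIANT_COLUMNS = ["variant_id", "gene", "chrom", "pos", "ref", "alt",
                   "normal_alt", "normal_depth", "primary_alt", "primary_depth"]
BIN_COLUMNS = ["chrom", "start", "end", "normal_depth", "tumor_depth"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "state", "n_sites",
                   "mean_folded_baf", "mean_logR"]


class SnpReadResult(NamedTuple):
    observations: list[SnpObservation]
    n_skipped: int


def _chrom_key(chrom: str) -> tuple:
    """Natural sort key so chr2 < chr10."""
    digits = "".join(ch for ch in chrom if ch.isdigit())
    return (chrom.rstrip("0123456789"), int(digits) if digits else -1)


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(path: PathLike, fmt: str = "auto",
                   tumor_sample: str = "TUMOR",
                   normal_sample: str = "NORMAL") -> SnpReadResult:
    """Read strain-informative SNP observations from VCF or TSV.

    Emits one observation per biallelic line; multi-allelic lines are skipped
    and counted in the result.  VCF input must carry an AD FORMAT field for
    both named samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "vcf":
        return _read_snp_vcf(path, tumor_sample, normal_sample)
    if fmt == "tsv":
        return _read_snp_tsv(path)
    raise ConfigurationError(f"unknown SNP table format {fmt!r}")


def _read_snp_vcf(path: Path, tumor_sample: str, normal_sample: str) -> SnpReadResult:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (normal_sample, tumor_sample):
        if name not in samples:
            raise ConfigurationError(
                f"sample {name!r} not in VCF (has {samples})")
    i_norm, i_tum = samples.index(normal_sample), samples.index(tumor_sample)

    observations: list[SnpObservation] = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise FormatError(f"missing AD field at {v.CHROM}:{v.POS}")
        nref, nalt = int(ad[i_norm][0]), int(ad[i_norm][1])
        tref, talt = int(ad[i_tum][0]), int(ad[i_tum][1])
        if min(nref, nalt, tref, talt) < 0:
            raise FormatError(f"negative AD count at {v.CHROM}:{v.POS}")
        observations.append(SnpObservation(
            chrom=v.CHROM, pos=v.POS, b6_allele=v.REF, s129_allele=v.ALT[0],
            normal_ref=nref, normal_alt=nalt, tumor_ref=tref, tumor_alt=talt))
    if not observations:
        log.warning("no usable SNP records in %s", path)
    if skipped:
        log.info("skipped %d multi-allelic lines in %s", skipped, path)
    return SnpReadResult(observations, skipped)


def _read_snp_tsv(path: Path) -> SnpReadResult:
    df = pd.read_csv(path, sep="\t")
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    observations = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after header
        try:
            observations.append(SnpObservation(
                chrom=str(row.chrom), pos=int(row.pos),
                b6_allele=str(row.b6_allele), s129_allele=str(row.s129_allele),
                normal_ref=int(row.normal_ref), normal_alt=int(row.normal_alt),
                tumor_ref=int(row.tumor_ref), tumor_alt=int(row.tumor_alt)))
        except ValueError as exc:
            raise FormatError(f"{path} line {line_no}: {exc}") from exc
    if not observations:
        log.warning("no usable SNP records in %s", path)
    return SnpReadResult(observations, 0)


def observations_to_frame(observations: Iterable[SnpObservation]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(o) for o in observations],
                        columns=SNP_COLUMNS)


def frame_to_observations(df: pd.DataFrame) -> list[SnpObservation]:
    return _read_frame_observations(df)


def _read_frame_observations(df: pd.DataFrame) -> list[SnpObservation]:
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"SNP frame missing columns {sorted(missing)}")
    return [SnpObservation(chrom=str(r.chrom), pos=int(r.pos),
                           b6_allele=str(r.b6_allele), s129_allele=str(r.s129_allele),
                           normal_ref=int(r.normal_ref), normal_alt=int(r.normal_alt),
                           tumor_ref=int(r.tumor_ref), tumor_alt=int(r.tumor_alt))
            for r in df.itertuples(index=False)]


def write_snp_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_snp_vcf(df: pd.DataFrame, path: PathLike,
                  tumor_sample: str = "TUMOR",
                  normal_sample: str = "NORMAL") -> None:
    """Write SNP observations as a minimal two-sample VCF 4.2 (AD, DP)."""
    lines = [_VCF_HEADER]
    for chrom in pd.unique(df["chrom"]):
        length = int(df.loc[df["chrom"] == chrom, "pos"].max()) + 1
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{normal_sample}\t{tumor_sample}\n")
    for r in df.itertuples(index=False):
        ndp = int(r.normal_ref) + int(r.normal_alt)
        tdp = int(r.tumor_ref) + int(r.tumor_alt)
        lines.append(
            f"{r.chrom}\t{int(r.pos)}\t.\t{r.b6_allele}\t{r.s129_allele}\t.\tPASS\t.\t"
            f"GT:AD:DP\t0/1:{int(r.normal_ref)},{int(r.normal_alt)}:{ndp}\t"
            f"./.:{int(r.tumor_ref)},{int(r.tumor_alt)}:{tdp}\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# somatic variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path: PathLike,
                       germline_bound: float = GERMLINE_VAF_BOUND) -> pd.DataFrame:
    """Read a (possibly paired) somatic variant table from TSV.

    Adds a ``germline_flagged`` column marking calls whose normal alt
    fraction exceeds ``germline_bound``; flagged calls are kept.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    count_cols = [c for c in df.columns if c.endswith(("_alt", "_depth"))]
    for col in count_cols:
        bad = df.index[df[col].fillna(0) < 0]
        if len(bad):
            raise FormatError(f"{path} line {bad[0] + 2}: negative count in {col}")
    for sample in ("normal", "primary", "relapse"):
        if f"{sample}_alt" in df.columns:
            over = df.index[df[f"{sample}_alt"].fillna(0) > df[f"{sample}_depth"].fillna(0)]
            if len(over):
                raise FormatError(
                    f"{path} line {over[0] + 2}: {sample} alt exceeds depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        nvaf = df["normal_alt"] / df["normal_depth"].replace(0, np.nan)
    df = df.copy()
    df["germline_flagged"] = (nvaf.fillna(0.0) > germline_bound)
    n_flagged = int(df["germline_flagged"].sum())
    if n_flagged:
        log.info("%d variant(s) flagged for germline contamination", n_flagged)
    return df


def write_variant_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def frame_to_variant_records(df: pd.DataFrame) -> list[SomaticVariantRecord]:
    records = []
    has_relapse = "relapse_alt" in df.columns
    for r in df.itertuples(index=False):
        records.append(SomaticVariantRecord(
            variant_id=str(r.variant_id), gene=str(r.gene), chrom=str(r.chrom),
            pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            normal_alt=int(r.normal_alt), normal_depth=int(r.normal_depth),
            primary_alt=int(r.primary_alt), primary_depth=int(r.primary_depth),
            relapse_alt=int(r.relapse_alt) if has_relapse else None,
            relapse_depth=int(r.relapse_depth) if has_relapse else None,
            germline_flagged=bool(getattr(r, "germline_flagged", False))))
    return records


# ---------------------------------------------------------------------------
# depth bins
# ---------------------------------------------------------------------------

def read_depth_bins(path: PathLike) -> pd.DataFrame:
    """Read a BED-like TSV of binned tumor/normal coverage."""
    df = pd.read_csv(path, sep="\t")
    missing = set(BIN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["end"] <= df["start"])
                   | (df["normal_depth"] < 0) | (df["tumor_depth"] < 0)]
    if len(bad):
        raise FormatError(f"{path} line {bad[0] + 2}: invalid bin")
    return df


def write_depth_bins(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def frame_to_bins(df: pd.DataFrame) -> list[DepthBin]:
    return [DepthBin(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                     normal_depth=float(r.normal_depth),
                     tumor_depth=float(r.tumor_depth))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# segments (BED-like with annotations)
# ---------------------------------------------------------------------------

def write_segments(segments: Sequence[Segment], path: PathLike) -> None:
    """Write classified segments as an annotated BED-like TSV.

    Requires segments sorted by (chrom, start); floats are written with
    repr-level precision so ``read_segments(write_segments(x)) == x``.
    """
    keys = [(_chrom_key(s.chrom), s.start) for s in segments]
    if keys != sorted(keys):
        raise FormatError("segments must be sorted by (chrom, start)")
    lines = ["\t".join(SEGMENT_COLUMNS) + "\n"]
    for s in segments:
        baf, logr = float(s.mean_folded_baf), float(s.mean_logr)
        lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{s.n_sites}\t"
                     f"{baf!r}\t{logr!r}\n")
    Path(path).write_text("".join(lines))


def read_segments(path: PathLike) -> list[Segment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [Segment(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                    state=str(r.state), n_sites=int(r.n_sites),
                    mean_folded_baf=float(r.mean_folded_baf),
                    mean_logr=float(r.mean_logR))
            for r in df.itertuples(index=False)]
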