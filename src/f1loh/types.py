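"""Domain records passed between pipeline stages.

All records are plain frozen dataclasses.  Coordinate conventions follow the
file formats they mirror: SNP and somatic-variant positions are 1-based
(VCF), depth bins and segments are 0-based half-open (BED).
"""
from __future__ import annotations

import dataclasses
import math
from typing import Optional

#: Segment copy states.
RETAINED_HET = "RETAINED_HET"
CN_LOH = "CN_LOH"
DELETION = "DELETION"
GAIN = "GAIN"
STATES = (RETAINED_HET, CN_LOH, DELETION, GAIN)

#: Parental haplotypes of the C57Bl/6 x 129Sv/Jae F1 background.
B6 = "B6"
S129 = "S129"
HAPLOTYPES = (B6, S129)

#: Primary/relapse comparison statuses.
ENRICHED = "ENRICHED"
DEPLETED = "DEPLETED"
STABLE = "STABLE"
DE_NOVO = "DE_NOVO"
LOST = "LOST"
STATUSES = (ENRICHED, DEPLETED, STABLE, DE_NOVO, LOST)


@dataclasses.dataclass(frozen=True)
class SnpObservation:
    """Tumor + matched-normal allele counts at one strain-informative germline SNP.

    ``b6_allele`` is the C57Bl/6 base (the reference strain, VCF REF) and
    ``s129_allele`` the 129Sv/Jae base (VCF ALT); counts are (ref, alt) ordered,
    i.e. ``*_alt`` counts reads carrying the 129 allele.
    """

    chrom: str
    pos: int
    b6_allele: str
    s129_allele: str
    normal_ref: int
    normal_alt: int
    tumor_ref: int
    tumor_alt: int

    def __post_init__(self) -> None:
        if self.b6_allele == self.s129_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: strain alleles must differ")
        for name in ("normal_ref", "normal_alt", "tumor_ref", "tumor_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.chrom}:{self.pos}: negative count {name}")

    @property
    def normal_counts(self) -> tuple[int, int]:
        return (self.normal_ref, self.normal_alt)

    @property
    def tumor_counts(self) -> tuple[int, int]:
        return (self.tumor_ref, self.tumor_alt)

    @property
    def normal_depth(self) -> int:
        return self.normal_ref + self.normal_alt

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref + self.tumor_alt


@dataclasses.dataclass(frozen=True)
class DepthBin:
    """Mean tumor/normal coverage over a genomic window (0-based half-open)."""

    chrom: str
    start: int
    end: int
    normal_depth: float
    tumor_depth: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.chrom}:{self.start}-{self.end}: empty bin")
        if self.normal_depth < 0 or self.tumor_depth < 0:
            raise ValueError(f"{self.chrom}:{self.start}-{self.end}: negative depth")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclasses.dataclass(frozen=True)
class SomaticVariantRecord:
    """One somatic point mutation with per-sample alt/total read counts."""

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    normal_alt: int
    normal_depth: int
    primary_alt: int
    primary_depth: int
    relapse_alt: Optional[int] = None
    relapse_depth: Optional[int] = None
    germline_flagged: bool = False

    def __post_init__(self) -> None:
        pairs = [("normal", self.normal_alt, self.normal_depth),
                 ("primary", self.primary_alt, self.primary_depth)]
        if self.relapse_alt is not None:
            pairs.append(("relapse", self.relapse_alt, self.relapse_depth or 0))
        for sample, alt, depth in pairs:
            if alt < 0 or depth < 0:
                raise ValueError(f"{self.variant_id}: negative {sample} count")
            if alt > depth:
                raise ValueError(f"{self.variant_id}: {sample} alt {alt} exceeds depth {depth}")


@dataclasses.dataclass(frozen=True)
class BafPoint:
    """Tumor strain-B (129) allele fraction at one usable informative SNP."""

    chrom: str
    pos: int
    baf: float
    tumor_depth: int
    normal_depth: int

    @property
    def folded_baf(self) -> float:
        """max(BAF, 1-BAF); removes the arbitrariness of the tracked allele."""
        return max(self.baf, 1.0 - self.baf)


@dataclasses.dataclass(frozen=True)
class LogRPoint:
    """Median-centered log2 tumor/normal coverage ratio of one depth bin."""

    chrom: str
    start: int
    end: int
    logr: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclasses.dataclass(frozen=True)
class Segment:
    """A classified genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    state: str
    n_sites: int
    mean_folded_baf: float
    mean_logr: float
    purity_estimate: Optional[float] = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown segment state {self.state!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position falls inside this segment."""
        return chrom == self.chrom and self.start <= pos - 1 < self.end


@dataclasses.dataclass(frozen=True)
class DuplicationCall:
    """Mutant-allele duplication (UPD) verdict for one somatic variant."""

    variant_id: str
    vaf: float
    segment_state: Optional[str]
    duplicated: bool
    mechanism: str


@dataclasses.dataclass(frozen=True)
class CloneGroup:
    """A group of somatic variants moving together in (primary, relapse) VAF space."""

    label: int
    members: tuple[str, ...]
    mean_vaf_primary: float
    mean_vaf_relapse: float
    ancestral: bool = False


def is_finite(x: float) -> bool:
    return x is not None and math.isfinite(x)
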