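"""B-allele-frequency and coverage log-ratio analysis of tumor/normal exomes.

On an F1-hybrid background every strain-informative SNP is germline
heterozygous, so the tumor's allele fraction at those sites (the BAF) sits
near 0.5 wherever both haplotypes are retained.  Somatic loss of one
haplotype pushes the folded BAF toward 1; the binned coverage log-ratio
(logR) separates the mechanisms:

* copy-neutral LOH / uniparental disomy: extreme folded BAF, neutral logR;
* hemizygous deletion: extreme folded BAF, negative logR;
* whole-chromosome gain (trisomy): moderate BAF shift, positive logR.

Classification is an explicit threshold table on (mean folded BAF, mean
logR) per segment; segments are whole chromosomes by default, with an
optional recursive binary segmentation for sub-chromosomal events.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, FormatError, NotEvaluableError
from .io import frame_to_bins, frame_to_observations
from .types import (BafPoint, CN_LOH, DELETION, DepthBin, DuplicationCall, GAIN,
                    LogRPoint, RETAINED_HET, Segment, SnpObservation)

log = logging.getLogger(__name__)

#: mutant-allele duplication rule: VAF above this inside CN-LOH.
DUPLICATION_VAF_THRESHOLD = 0.8

MECHANISM_DUPLICATION = "copy-neutral LOH with increased mutant-allele dosage"
MECHANISM_HEMIZYGOUS = "hemizygous loss of the wild-type allele"
MECHANISM_HET = "heterozygous / subclonal"
MECHANISM_UNASSIGNED = "unassigned (outside all segments)"


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Decision cuts for the (folded BAF, logR) classification table.

    The neutral logR band must not overlap the deletion/gain cuts.
    Defaults keep power down to ~70% purity: CN-LOH at purity p has expected
    folded BAF (1+p)/2 and logR 0; a pure hemizygous deletion has logR -1;
    a pure trisomy log2(1.5) = 0.585.
    """

    baf_loh: float = 0.85
    logr_neutral: float = 0.2
    logr_del: float = -0.35
    logr_gain: float = 0.3

    def __post_init__(self) -> None:
        if not 0.5 <= self.baf_loh <= 1.0:
            raise ConfigurationError("baf_loh must lie in [0.5, 1]")
        if self.logr_neutral <= 0:
            raise ConfigurationError("logr_neutral must be positive")
        if self.logr_del >= -self.logr_neutral:
            raise ConfigurationError(
                "neutral band overlaps the deletion cut: require logr_del < -logr_neutral")
        if self.logr_gain <= self.logr_neutral:
            raise ConfigurationError(
                "neutral band overlaps the gain cut: require logr_gain > logr_neutral")


@dataclasses.dataclass
class BafTrack:
    """Usable BAF points plus gate-exclusion tallies."""

    points: list[BafPoint]
    n_excluded_depth: int = 0
    n_excluded_het: int = 0

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)


def compute_baf(observations: Union[Iterable[SnpObservation], pd.DataFrame],
                min_depth: int = 20,
                het_band: tuple[float, float] = (0.25, 0.75)) -> BafTrack:
    """Tumor BAF at sites passing the germline-heterozygosity and depth gates.

    A site is usable only if the normal BAF lies in ``het_band`` (confirming
    the germline het genotype) and BOTH samples reach ``min_depth`` reads.
    Excluded sites are counted, never silently dropped.
    """
    if isinstance(observations, pd.DataFrame):
        observations = frame_to_observations(observations)
    lo, hi = het_band
    points: list[BafPoint] = []
    n_depth = n_het = 0
    chroms_seen: set[str] = set()
    chroms_used: set[str] = set()
    for obs in observations:
        chroms_seen.add(obs.chrom)
        if obs.normal_depth < min_depth or obs.tumor_depth < min_depth:
            n_depth += 1
            continue
        normal_baf = obs.normal_alt / obs.normal_depth
        if not lo <= normal_baf <= hi:
            n_het += 1
            continue
        chroms_used.add(obs.chrom)
        points.append(BafPoint(chrom=obs.chrom, pos=obs.pos,
                               baf=obs.tumor_alt / obs.tumor_depth,
                               tumor_depth=obs.tumor_depth,
                               normal_depth=obs.normal_depth))
    for chrom in sorted(chroms_seen - chroms_used):
        log.warning("no usable BAF sites on %s; track is empty there", chrom)
    return BafTrack(points, n_excluded_depth=n_depth, n_excluded_het=n_het)


def compute_logR(bins: Union[Iterable[DepthBin], pd.DataFrame]) -> list[LogRPoint]:
    """Per-bin log2 tumor/normal coverage ratio, median-centered genome-wide.

    Bins with zero depth in either sample are excluded (the ratio is not
    finite there); an input whose normal depths are all zero is fatal.
    Median centering assumes a majority-diploid genome.
    """
    if isinstance(bins, pd.DataFrame):
        bins = frame_to_bins(bins)
    bins = list(bins)
    if bins and all(b.normal_depth == 0 for b in bins):
        raise FormatError("all normal depths are zero; cannot form log ratios")
    usable = [b for b in bins if b.normal_depth > 0 and b.tumor_depth > 0]
    if not usable:
        return []
    raw = np.log2([b.tumor_depth / b.normal_depth for b in usable])
    centered = raw - np.median(raw)
    return [LogRPoint(chrom=b.chrom, start=b.start, end=b.end, logr=float(r))
            for b, r in zip(usable, centered)]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _classify(mean_folded_baf: float, mean_logr: float,
              thresholds: Thresholds) -> tuple[str, bool]:
    """(state, ambiguous) from the decision table.

    A segment with no finite logR evidence is judged at logR 0 but flagged
    ambiguous.  Combinations matching no table row (e.g. extreme BAF with
    logR in the gap between the neutral band and the deletion cut) fall back
    to RETAINED_HET with the ambiguous flag set.
    """
    ambiguous = False
    if not math.isfinite(mean_logr):
        mean_logr, ambiguous = 0.0, True
    t = thresholds
    if mean_folded_baf >= t.baf_loh:
        if abs(mean_logr) <= t.logr_neutral:
            return CN_LOH, ambiguous
        if mean_logr <= t.logr_del:
            return DELETION, ambiguous
        return RETAINED_HET, True
    if mean_logr >= t.logr_gain:
        return GAIN, ambiguous
    if abs(mean_logr) <= t.logr_neutral:
        return RETAINED_HET, ambiguous
    return RETAINED_HET, True


def classify_segment(mean_folded_baf: float, mean_logr: float,
                     thresholds: Thresholds = Thresholds()) -> str:
    """Copy state from segment summary statistics.

    Decision table (defaults): folded BAF >= 0.85 with |logR| <= 0.2 is
    CN_LOH; folded BAF >= 0.85 with logR <= -0.35 is DELETION; folded BAF
    below the cut with logR >= +0.3 is GAIN; everything else RETAINED_HET.
    """
    state, _ = _classify(mean_folded_baf, mean_logr, thresholds)
    return state


def purity_from_baf(segment: Segment) -> float:
    """Tumor purity implied by a clonal CN-LOH segment: p = 2*BAF_folded - 1.

    Inverts the expected folded BAF (1+p)/2 of copy-neutral LOH carried by
    all tumor cells; a subclonal event yields the event's cell fraction
    instead, making this a lower bound on purity.
    """
    if segment.state != CN_LOH:
        raise NotEvaluableError(
            f"purity from BAF applies only to CN_LOH segments, not {segment.state}")
    return float(np.clip(2.0 * segment.mean_folded_baf - 1.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _check_sorted(points: Sequence, what: str) -> None:
    keys = [( _natural(p.chrom), getattr(p, "pos", getattr(p, "start", 0))) for p in points]
    if keys != sorted(keys):
        raise FormatError(f"{what} must be sorted by (chrom, position)")


def _natural(chrom: str) -> tuple:
    digits = "".join(ch for ch in chrom if ch.isdigit())
    return (chrom.rstrip("0123456789"), int(digits) if digits else -1)


def _split_indices(folded: np.ndarray, min_sites: int,
                   split_threshold: float) -> list[int]:
    """Recursive binary segmentation; returns sorted interior breakpoints.

    Splits at the index maximizing the absolute difference of folded-BAF
    means between the two sides, accepting when the difference exceeds the
    threshold and both sides keep ``min_sites`` points.  Ties break leftmost.
    """
    n = folded.size
    if n < 2 * min_sites:
        return []
    csum = np.cumsum(folded)
    total = csum[-1]
    ks = np.arange(min_sites, n - min_sites + 1)
    left = csum[ks - 1] / ks
    right = (total - csum[ks - 1]) / (n - ks)
    diffs = np.abs(left - right)
    best = int(np.argmax(diffs))  # leftmost maximum
    if diffs[best] <= split_threshold:
        return []
    k = int(ks[best])
    return ([*_split_indices(folded[:k], min_sites, split_threshold), k]
            + [k + i for i in _split_indices(folded[k:], min_sites, split_threshold)])


def segment_track(baf_points: Sequence[BafPoint],
                  logr_points: Sequence[LogRPoint] = (),
                  min_sites: int = 10,
                  mode: str = "chromosome",
                  split_threshold: float = 0.15,
                  thresholds: Thresholds = Thresholds()) -> list[Segment]:
    """Partition the BAF track and classify each segment.

    ``chromosome`` mode emits one segment per chromosome (matching
    whole-chromosome allele-frequency plots); ``binary_segmentation``
    recursively splits on folded-BAF mean differences.  Deterministic; a
    segment with fewer than ``min_sites`` points is flagged ambiguous.
    """
    if min_sites < 2:
        raise ConfigurationError("min_sites must be at least 2")
    if mode not in ("chromosome", "binary_segmentation"):
        raise ConfigurationError(f"unknown segmentation mode {mode!r}")
    baf_points = list(baf_points)
    logr_points = list(logr_points)
    _check_sorted(baf_points, "BAF track")
    _check_sorted(logr_points, "logR track")

    by_chrom: dict[str, list[BafPoint]] = {}
    for p in baf_points:
        by_chrom.setdefault(p.chrom, []).append(p)
    logr_by_chrom: dict[str, list[LogRPoint]] = {}
    for r in logr_points:
        logr_by_chrom.setdefault(r.chrom, []).append(r)

    segments: list[Segment] = []
    chroms = sorted(set(by_chrom) | set(logr_by_chrom), key=_natural)
    for chrom in chroms:
        pts = by_chrom.get(chrom, [])
        lrs = logr_by_chrom.get(chrom, [])
        chrom_end = max([p.pos for p in pts] + [r.end for r in lrs])
        if not pts:
            log.warning("no BAF evidence on %s; emitting logR-only segment", chrom)
            boundaries = [(0, chrom_end, [])]
        elif mode == "chromosome":
            boundaries = [(0, chrom_end, pts)]
        else:
            folded = np.array([p.folded_baf for p in pts])
            cuts = _split_indices(folded, min_sites, split_threshold)
            edges = [0, *cuts, len(pts)]
            boundaries = []
            for i, j in zip(edges, edges[1:]):
                start = 0 if i == 0 else (pts[i - 1].pos + pts[i].pos) // 2
                end = chrom_end if j == len(pts) else (pts[j - 1].pos + pts[j].pos) // 2
                boundaries.append((start, end, pts[i:j]))
        for start, end, seg_pts in boundaries:
            seg_lrs = [r.logr for r in lrs if start <= r.midpoint < end]
            mean_logr = float(np.mean(seg_lrs)) if seg_lrs else float("nan")
            mean_baf = (float(np.mean([p.folded_baf for p in seg_pts]))
                        if seg_pts else 0.5)
            state, ambiguous = _classify(mean_baf, mean_logr, thresholds)
            if len(seg_pts) < min_sites:
                ambiguous = True
            seg = Segment(chrom=chrom, start=int(start), end=int(end), state=state,
                          n_sites=len(seg_pts), mean_folded_baf=mean_baf,
                          mean_logr=mean_logr, ambiguous=ambiguous)
            if state == CN_LOH:
                seg = dataclasses.replace(seg, purity_estimate=purity_from_baf(seg))
            segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# mutant-allele duplication (UPD) calling
# ---------------------------------------------------------------------------

def call_mutant_duplication(variant: Union[Mapping, "pd.Series"],
                            segments: Sequence[Segment],
                            sample: str = "primary",
                            vaf_threshold: float = DUPLICATION_VAF_THRESHOLD
                            ) -> DuplicationCall:
    """Decide whether a somatic mutation's mutant allele was duplicated by UPD.

    TRUE iff the VAF exceeds ``vaf_threshold`` AND the enclosing segment is
    CN_LOH.  The same VAF inside a DELETION segment is explained by
    hemizygous loss instead, not duplication.  A variant outside all
    segments yields an unassigned (negative) call with a warning.
    """
    chrom, pos = str(variant["chrom"]), int(variant["pos"])
    alt, depth = int(variant[f"{sample}_alt"]), int(variant[f"{sample}_depth"])
    if depth == 0:
        raise NotEvaluableError(f"{variant['variant_id']}: zero depth in {sample}")
    vaf_value = alt / depth
    enclosing = [s for s in segments if s.contains(chrom, pos)]
    if not enclosing:
        log.warning("variant %s at %s:%d falls outside all segments",
                    variant["variant_id"], chrom, pos)
        return DuplicationCall(variant_id=str(variant["variant_id"]), vaf=vaf_value,
                               segment_state=None, duplicated=False,
                               mechanism=MECHANISM_UNASSIGNED)
    state = enclosing[0].state
    high = vaf_value > vaf_threshold
    if high and state == CN_LOH:
        mechanism, duplicated = MECHANISM_DUPLICATION, True
    elif high and state == DELETION:
        mechanism, duplicated = MECHANISM_HEMIZYGOUS, False
    else:
        mechanism, duplicated = MECHANISM_HET, False
    return DuplicationCall(variant_id=str(variant["variant_id"]), vaf=vaf_value,
                           segment_state=state, duplicated=duplicated,
                           mechanism=mechanism)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class AllelicImbalanceCaller(BaseEstimator):
    """Segment-state caller over (BAF, logR) evidence, scikit-learn style.

    ``fit`` consumes SNP observations and depth bins and exposes the fitted
    tracks and classified segments; ``predict`` maps genomic positions to
    segment states.  All thresholds are constructor parameters, so the
    caller composes with sklearn model-selection utilities.
    """

    def __init__(self, min_depth: int = 20, het_low: float = 0.25,
                 het_high: float = 0.75, baf_loh: float = 0.85,
                 logr_neutral: float = 0.2, logr_del: float = -0.35,
                 logr_gain: float = 0.3, min_sites: int = 10,
                 mode: str = "chromosome", split_threshold: float = 0.15,
                 dup_vaf_threshold: float = DUPLICATION_VAF_THRESHOLD):
        self.min_depth = min_depth
        self.het_low = het_low
        self.het_high = het_high
        self.baf_loh = baf_loh
        self.logr_neutral = logr_neutral
        self.logr_del = logr_del
        self.logr_gain = logr_gain
        self.min_sites = min_sites
        self.mode = mode
        self.split_threshold = split_threshold
        self.dup_vaf_threshold = dup_vaf_threshold

    def _thresholds(self) -> Thresholds:
        return Thresholds(baf_loh=self.baf_loh, logr_neutral=self.logr_neutral,
                          logr_del=self.logr_del, logr_gain=self.logr_gain)

    def fit(self, observations, bins=None, y=None) -> "AllelicImbalanceCaller":
        """Compute tracks and segments from SNP observations and depth bins."""
        thresholds = self._thresholds()  # validates before any work
        self.baf_track_ = compute_baf(observations, min_depth=self.min_depth,
                                      het_band=(self.het_low, self.het_high))
        self.logr_points_ = (compute_logR(bins) if bins is not None else [])
        self.segments_ = segment_track(self.baf_track_.points, self.logr_points_,
                                       min_sites=self.min_sites, mode=self.mode,
                                       split_threshold=self.split_threshold,
                                       thresholds=thresholds)
        cn_loh = [s.purity_estimate for s in self.segments_
                  if s.state == CN_LOH and s.purity_estimate is not None]
        self.purity_estimate_ = max(cn_loh) if cn_loh else float("nan")
        return self

    def predict(self, X) -> np.ndarray:
        """Segment state for each (chrom, pos) row of ``X``."""
        if not hasattr(self, "segments_"):
            raise NotEvaluableError("call fit before predict")
        if isinstance(X, pd.DataFrame):
            rows = [(str(r.chrom), int(r.pos)) for r in X.itertuples(index=False)]
        else:
            rows = [(str(c), int(p)) for c, p in X]
        states = []
        for chrom, pos in rows:
            hit = [s.state for s in self.segments_ if s.contains(chrom, pos)]
            states.append(hit[0] if hit else RETAINED_HET)
        return np.array(states, dtype=object)

    def call_duplications(self, variants: pd.DataFrame,
                          sample: str = "primary") -> list[DuplicationCall]:
        """Mutant-duplication call for every row of a variant table."""
        if not hasattr(self, "segments_"):
            raise NotEvaluableError("call fit before call_duplications")
        return [call_mutant_duplication(row, self.segments_, sample=sample,
                                        vaf_threshold=self.dup_vaf_threshold)
                for _, row in variants.iterrows()]
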