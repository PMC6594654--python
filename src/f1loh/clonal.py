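"""Primary-versus-relapse variant allele frequency comparison and clone grouping.

Under targeted-therapy selection a leukemia's relapse is drawn from
pre-existing or newly arising subclones, visible as per-mutation VAF shifts
between the paired exomes.  Each variant's primary/relapse counts are
compared with a two-sided Fisher exact test; p-values are Benjamini-Hochberg
adjusted within the pair, and each variant is labeled ENRICHED, DEPLETED,
STABLE, DE_NOVO (absent from the primary) or LOST (absent at relapse).
Variants are then grouped into clones by average-linkage clustering in
(primary VAF, relapse VAF) space.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, NotEvaluableError
from .types import (CloneGroup, DE_NOVO, DEPLETED, DuplicationCall, ENRICHED,
                    LOST, STABLE)

log = logging.getLogger(__name__)

#: alt reads below this operationalize "not detectable" at exome depth.
DEFAULT_LOD_READS = 3

DIR_ENRICHED = "enriched"
DIR_DEPLETED = "depleted"
DIR_STABLE = "stable"
DIR_NOT_TESTABLE = "not_testable"


def round3(x: float) -> float:
    """Round half-up to 3 decimals, the reporting precision for VAFs."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"),
                                                  rounding=ROUND_HALF_UP))


def vaf(alt_count: int, total_depth: int) -> float:
    """Variant allele frequency, rounded to 3 decimals for reporting.

    Full-precision ratios are used internally throughout the module; this is
    the reported value.  Zero total depth is an error, not a zero.
    """
    if total_depth == 0:
        raise NotEvaluableError("VAF undefined at zero depth")
    if not 0 <= alt_count <= total_depth:
        raise ValueError(f"alt count {alt_count} outside [0, {total_depth}]")
    return round3(alt_count / total_depth)


def binomial_ci(alt_count: int, total_depth: int,
                confidence: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial proportion."""
    if not 0.0 < confidence < 1.0:
        raise ConfigurationError("confidence must lie in (0, 1)")
    if total_depth == 0:
        raise NotEvaluableError("CI undefined at zero depth")
    if not 0 <= alt_count <= total_depth:
        raise ValueError(f"alt count {alt_count} outside [0, {total_depth}]")
    alpha = 1.0 - confidence
    lower = (0.0 if alt_count == 0
             else float(stats.beta.ppf(alpha / 2, alt_count,
                                       total_depth - alt_count + 1)))
    upper = (1.0 if alt_count == total_depth
             else float(stats.beta.ppf(1 - alpha / 2, alt_count + 1,
                                       total_depth - alt_count)))
    return (lower, upper)


def compare_pair(primary: tuple[int, int], relapse: tuple[int, int]
                 ) -> tuple[float, str]:
    """Two-sided Fisher exact test of a variant's primary vs relapse counts.

    ``primary`` and ``relapse`` are (alt, total) count pairs.  Returns
    (p, direction) with direction from the raw VAF comparison; a pair with
    zero depth in both samples is not testable (p = NaN).
    """
    alt_p, tot_p = primary
    alt_r, tot_r = relapse
    for alt, tot, name in ((alt_p, tot_p, "primary"), (alt_r, tot_r, "relapse")):
        if not 0 <= alt <= tot:
            raise ValueError(f"{name}: alt {alt} outside [0, {tot}]")
    if tot_p == 0 and tot_r == 0:
        return (float("nan"), DIR_NOT_TESTABLE)
    table = [[alt_p, tot_p - alt_p], [alt_r, tot_r - alt_r]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    vp = alt_p / tot_p if tot_p else 0.0
    vr = alt_r / tot_r if tot_r else 0.0
    if vr > vp:
        direction = DIR_ENRICHED
    elif vr < vp:
        direction = DIR_DEPLETED
    else:
        direction = DIR_STABLE
    return (p, direction)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values; NaNs pass through untouched."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def classify_status(primary: tuple[int, int], relapse: tuple[int, int],
                    q: float, alpha: float = 0.05,
                    lod_reads: int = DEFAULT_LOD_READS) -> str:
    """Clonal-status label for one variant given its BH-adjusted q.

    DE_NOVO: significant shift with primary alt reads below the limit of
    detection and the mutation present at relapse; LOST is the mirror image;
    otherwise ENRICHED/DEPLETED by direction when significant, else STABLE.
    """
    alt_p, tot_p = primary
    alt_r, tot_r = relapse
    vp = alt_p / tot_p if tot_p else 0.0
    vr = alt_r / tot_r if tot_r else 0.0
    significant = math.isfinite(q) and q < alpha
    if not significant:
        return STABLE
    if alt_p < lod_reads and vr > 0:
        return DE_NOVO
    if alt_r < lod_reads and vp > 0:
        return LOST
    return ENRICHED if vr > vp else DEPLETED


def analyze_pair(variants: pd.DataFrame, alpha: float = 0.05,
                 lod_reads: int = DEFAULT_LOD_READS,
                 confidence: float = 0.95) -> pd.DataFrame:
    """Full paired analysis of a variant table with primary+relapse counts.

    Returns one row per variant: reported VAFs, Clopper-Pearson intervals,
    Fisher p, BH q (adjusted across the variants of this pair) and status.
    """
    required = {"variant_id", "primary_alt", "primary_depth",
                "relapse_alt", "relapse_depth"}
    missing = required - set(variants.columns)
    if missing:
        raise ConfigurationError(f"variant table missing columns {sorted(missing)}")
    rows = []
    for _, r in variants.iterrows():
        prim = (int(r["primary_alt"]), int(r["primary_depth"]))
        rel = (int(r["relapse_alt"]), int(r["relapse_depth"]))
        p, direction = compare_pair(prim, rel)
        row = {
            "variant_id": r["variant_id"],
            "gene": r.get("gene", ""),
            "vaf_primary": vaf(*prim) if prim[1] else float("nan"),
            "vaf_relapse": vaf(*rel) if rel[1] else float("nan"),
            "p": p, "direction": direction,
            "_prim": prim, "_rel": rel,
        }
        row["ci_primary_low"], row["ci_primary_high"] = (
            binomial_ci(*prim, confidence) if prim[1] else (float("nan"),) * 2)
        row["ci_relapse_low"], row["ci_relapse_high"] = (
            binomial_ci(*rel, confidence) if rel[1] else (float("nan"),) * 2)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["status"] = [
        classify_status(r["_prim"], r["_rel"], r["q"], alpha=alpha,
                        lod_reads=lod_reads)
        if r["direction"] != DIR_NOT_TESTABLE else DIR_NOT_TESTABLE.upper()
        for _, r in out.iterrows()
    ]
    return out.drop(columns=["_prim", "_rel"])


def detect_heterozygosity_reacquisition(
        primary_call: DuplicationCall,
        relapse_alt: int, relapse_total: int,
        purity: float = 1.0,
        het_band: tuple[float, float] = (0.4, 0.6),
        confidence: float = 0.95) -> bool:
    """Did a duplicated mutant allele return to heterozygosity at relapse?

    TRUE iff the primary call is a mutant-allele duplication (high VAF inside
    CN-LOH) and the relapse VAF's confidence interval, rescaled to the pure
    tumor by dividing by ``purity``, overlaps the heterozygous band.
    """
    if primary_call.segment_state is None:
        raise NotEvaluableError(
            f"{primary_call.variant_id}: no segment context in the primary sample")
    if not 0.0 < purity <= 1.0:
        raise ConfigurationError("purity must lie in (0, 1]")
    if not primary_call.duplicated:
        return False
    lo, hi = binomial_ci(relapse_alt, relapse_total, confidence)
    lo, hi = min(lo / purity, 1.0), min(hi / purity, 1.0)
    band_lo, band_hi = het_band
    return lo <= band_hi and hi >= band_lo


def sanger_af(mut_peak_height: float, wt_peak_height: float) -> float:
    """Allele fraction from Sanger trace peak intensities: mut / (mut + wt)."""
    if mut_peak_height < 0 or wt_peak_height < 0:
        raise ValueError("peak heights must be non-negative")
    total = mut_peak_height + wt_peak_height
    if total == 0:
        raise NotEvaluableError("allele fraction undefined with two zero peaks")
    return mut_peak_height / total


# ---------------------------------------------------------------------------
# clone grouping
# ---------------------------------------------------------------------------

def group_clones(vaf_primary: Sequence[float], vaf_relapse: Sequence[float],
                 ids: Optional[Sequence[str]] = None,
                 linkage_cutoff: float = 0.1) -> list[CloneGroup]:
    """Group variants into clones by their (primary, relapse) VAF trajectory.

    Average-linkage hierarchical clustering with Euclidean distance, cut at
    ``linkage_cutoff``.  Groups are labeled in order of their lowest member
    id (deterministic); the group whose mean VAF is maximal in BOTH samples,
    if one exists, is flagged ancestral.  This is deliberately a simple
    two-sample VAF clustering, not a phylogeny reconstruction.
    """
    X = np.column_stack([np.asarray(vaf_primary, float),
                         np.asarray(vaf_relapse, float)])
    n = X.shape[0]
    if n == 0:
        raise ConfigurationError("need at least one variant to group")
    if ids is None:
        ids = [f"v{i + 1}" for i in range(n)]
    ids = [str(i) for i in ids]
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(X, method="average", metric="euclidean")
        labels = fcluster(Z, t=linkage_cutoff, criterion="distance")
    raw_groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        raw_groups.setdefault(int(lab), []).append(i)
    # deterministic relabeling: order groups by their smallest member id
    ordered = sorted(raw_groups.values(), key=lambda idx: min(ids[i] for i in idx))
    groups = []
    for label, idx in enumerate(ordered, start=1):
        members = tuple(sorted(ids[i] for i in idx))
        groups.append(CloneGroup(label=label, members=members,
                                 mean_vaf_primary=float(X[idx, 0].mean()),
                                 mean_vaf_relapse=float(X[idx, 1].mean())))
    max_p = max(g.mean_vaf_primary for g in groups)
    max_r = max(g.mean_vaf_relapse for g in groups)
    out = []
    for g in groups:
        ancestral = (math.isclose(g.mean_vaf_primary, max_p)
                     and math.isclose(g.mean_vaf_relapse, max_r))
        out.append(dataclasses.replace(g, ancestral=ancestral))
    return out


def clone_labels(groups: Sequence[CloneGroup], ids: Sequence[str]) -> np.ndarray:
    """Per-variant group label array aligned with ``ids``."""
    lookup = {m: g.label for g in groups for m in g.members}
    return np.array([lookup[str(i)] for i in ids])


# ---------------------------------------------------------------------------
# estimator facades
# ---------------------------------------------------------------------------

class PairedVafAnalyzer(BaseEstimator):
    """Sklearn-style wrapper over :func:`analyze_pair`.

    ``fit`` consumes a paired variant table; fitted attributes expose the
    per-variant results and statuses.
    """

    def __init__(self, alpha: float = 0.05, lod_reads: int = DEFAULT_LOD_READS,
                 confidence: float = 0.95):
        self.alpha = alpha
        self.lod_reads = lod_reads
        self.confidence = confidence

    def fit(self, variants: pd.DataFrame, y=None) -> "PairedVafAnalyzer":
        self.results_ = analyze_pair(variants, alpha=self.alpha,
                                     lod_reads=self.lod_reads,
                                     confidence=self.confidence)
        self.statuses_ = self.results_["status"].to_numpy()
        return self

    def fit_predict(self, variants: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(variants).statuses_


class CloneGrouper(ClusterMixin, BaseEstimator):
    """Average-linkage clone grouping as a sklearn clusterer.

    ``X`` is an (n_variants, 2) array of (primary, relapse) VAFs; ``labels_``
    holds deterministic group labels and ``groups_`` the CloneGroup records.
    """

    def __init__(self, linkage_cutoff: float = 0.1):
        self.linkage_cutoff = linkage_cutoff

    def fit(self, X, y=None) -> "CloneGrouper":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ConfigurationError("X must be an (n_variants, 2) VAF array")
        ids = [f"v{i + 1:06d}" for i in range(X.shape[0])]
        self.groups_ = group_clones(X[:, 0], X[:, 1], ids=ids,
                                    linkage_cutoff=self.linkage_cutoff)
        self.labels_ = clone_labels(self.groups_, ids)
        return self
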