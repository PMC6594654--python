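"""Synthetic F1-hybrid tumor/normal exome read counts with known ground truth.

The generator emulates the data a whole-exome pipeline sees for a leukemia
arising on a C57Bl/6 x 129Sv/Jae F1 background: every strain-informative SNP
is germline heterozygous, so somatic loss of one parental haplotype is
directly observable as a B-allele-frequency shift.  Simulated samples are a
matched normal plus a primary/relapse tumor pair that share clonal structure
but differ in clone fractions (and possibly purity).

The model is a cell-population mixture: a sample is a mix of normal cells
(diploid, heterozygous, mutation-free) and tumor clones, each clone carrying
a configured set of copy-number events (copy-neutral LOH, hemizygous
deletion, whole-arm/chromosome gain) and somatic point mutations with a
mutant-allele multiplicity.  Expected allele fractions are exact population
averages of allele copies; observed read counts are binomial draws at
Poisson (optionally negative-binomial) depths.

Haplotype phase exists only inside the generator; emitted tables carry
per-site counts, which is all the downstream analysis uses.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, TruthError
from .types import B6, CN_LOH, DELETION, GAIN, HAPLOTYPES, S129

_EVENT_KINDS = (CN_LOH, DELETION, GAIN)
_BASES = np.array(list("ACGT"))
#: pseudo-sites averaged per depth bin; controls bin-level noise.
_BIN_PSEUDO_SITES = 25

# Fixed per-role RNG substream indices: adding chromosomes or samples never
# perturbs draws of an existing (role, chromosome) stream.
_ROLE_SITES = 0
_ROLE_SNP = {"normal": 1, "primary": 2, "relapse": 3}
_ROLE_BIN = {"normal": 4, "primary": 5, "relapse": 6}
_ROLE_VARIANT_META = 7
_ROLE_VARIANT = {"normal": 8, "primary": 9, "relapse": 10}

TUMOR_SAMPLES = ("primary", "relapse")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclasses.dataclass(frozen=True)
class CnEvent:
    """A clonal copy-number event on one chromosome (1-based inclusive interval).

    ``haplotype`` names the *retained* parental haplotype for CN_LOH and
    DELETION and the *duplicated* one for GAIN.  ``clone_ids`` lists the tumor
    clones carrying the event.
    """

    chrom: str
    start: int
    end: int
    kind: str
    haplotype: str = S129
    clone_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if self.haplotype not in HAPLOTYPES:
            raise ConfigurationError(f"unknown haplotype {self.haplotype!r}")
        if self.start >= self.end:
            raise ConfigurationError(
                f"event {self.chrom}:{self.start}-{self.end}: start must precede end")
        object.__setattr__(self, "clone_ids", tuple(self.clone_ids))

    @property
    def copy_numbers(self) -> tuple[int, int]:
        """(B6 copies, 129 copies) in a cell carrying the event."""
        if self.kind == CN_LOH:
            return (2, 0) if self.haplotype == B6 else (0, 2)
        if self.kind == DELETION:
            return (1, 0) if self.haplotype == B6 else (0, 1)
        return (2, 1) if self.haplotype == B6 else (1, 2)  # GAIN

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def to_dict(self) -> dict:
        return {"chrom": self.chrom, "start": self.start, "end": self.end,
                "kind": self.kind, "haplotype": self.haplotype,
                "clone_ids": list(self.clone_ids)}


@dataclasses.dataclass(frozen=True)
class SomaticMutation:
    """A somatic point substitution carried by a clone.

    ``multiplicity`` is the number of mutant copies per carrying cell: 1 for a
    heterozygous hit, 2 when the mutant allele was duplicated by CN-LOH.
    """

    chrom: str
    pos: int
    gene: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity not in (1, 2):
            raise TruthError(f"{self.gene}: multiplicity must be 1 or 2")

    def to_dict(self) -> dict:
        return {"chrom": self.chrom, "pos": self.pos, "gene": self.gene,
                "multiplicity": self.multiplicity}


@dataclasses.dataclass(frozen=True)
class CloneSpec:
    """One tumor clone with its per-sample cellular fraction (of tumor cells)."""

    clone_id: str
    fraction_primary: float
    fraction_relapse: float
    mutations: tuple[SomaticMutation, ...] = ()

    def __post_init__(self) -> None:
        if self.fraction_primary < 0 or self.fraction_relapse < 0:
            raise ConfigurationError(f"clone {self.clone_id}: negative fraction")
        object.__setattr__(self, "mutations", tuple(self.mutations))

    def fraction(self, sample: str) -> float:
        if sample == "primary":
            return self.fraction_primary
        if sample == "relapse":
            return self.fraction_relapse
        raise ConfigurationError(f"unknown tumor sample {sample!r}")

    def to_dict(self) -> dict:
        return {"clone_id": self.clone_id,
                "fraction_primary": self.fraction_primary,
                "fraction_relapse": self.fraction_relapse,
                "mutations": [m.to_dict() for m in self.mutations]}


@dataclasses.dataclass
class SimConfig:
    """Full specification of one simulated tumor/normal trio.

    snp_density is informative SNPs per Mb; depths are per-site means;
    purity is the tumor-cell fraction of each tumor sample.  target_mb is the
    callable exome size used for burden accounting downstream.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = 60_000_000
    snp_density: float = 1.0
    mean_depth_normal: float = 100.0
    mean_depth_tumor: float = 100.0
    purity_primary: float = 0.9
    purity_relapse: float = 0.9
    events: tuple[CnEvent, ...] = ()
    clones: tuple[CloneSpec, ...] = ()
    target_mb: float = 50.0
    bin_size_bp: int = 2_000_000
    error_rate: float = 0.001
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        self.events = tuple(self.events)
        self.clones = tuple(self.clones)

    # -- structure ---------------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def purity(self, sample: str) -> float:
        if sample == "primary":
            return self.purity_primary
        if sample == "relapse":
            return self.purity_relapse
        raise ConfigurationError(f"unknown tumor sample {sample!r}")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not 0.0 <= self.purity_primary <= 1.0 or not 0.0 <= self.purity_relapse <= 1.0:
            raise ConfigurationError("purity must lie in [0, 1]")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be positive")
        if self.mean_depth_normal <= 0 or self.mean_depth_tumor <= 0:
            raise ConfigurationError("mean depths must be positive")
        if self.n_chromosomes < 1 or self.chrom_length_bp < self.bin_size_bp:
            raise ConfigurationError("need at least one chromosome spanning one bin")
        if self.target_mb <= 0:
            raise ConfigurationError("target_mb must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must lie in [0, 0.5)")
        if self.overdispersion < 0:
            raise ConfigurationError("overdispersion must be non-negative")

        for sample in TUMOR_SAMPLES:
            total = sum(c.fraction(sample) for c in self.clones)
            if total > 1.0 + 1e-9:
                raise ConfigurationError(
                    f"clone fractions in {sample} sum to {total:.3f} > 1")

        chroms = set(self.chromosomes)
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("clone ids must be unique")
        for ev in self.events:
            if ev.chrom not in chroms:
                raise ConfigurationError(f"event on unknown chromosome {ev.chrom}")
            for cid in ev.clone_ids:
                if cid not in ids:
                    raise ConfigurationError(f"event names unknown clone {cid!r}")

        # events carried by one clone may not overlap on a chromosome
        by_key: dict[tuple[str, str], list[CnEvent]] = {}
        for ev in self.events:
            for cid in ev.clone_ids:
                by_key.setdefault((cid, ev.chrom), []).append(ev)
        for (cid, chrom), evs in by_key.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start <= a.end:
                    raise ConfigurationError(
                        f"overlapping events for clone {cid} on {chrom}: "
                        f"{a.start}-{a.end} collides with {b.start}-{b.end}")

        for clone in self.clones:
            for mut in clone.mutations:
                if mut.chrom not in chroms:
                    raise ConfigurationError(
                        f"mutation {mut.gene} on unknown chromosome {mut.chrom}")
                cb6, cs129 = self.clone_copy_numbers(clone.clone_id, mut.chrom, mut.pos)
                total = cb6 + cs129
                if mut.multiplicity > total:
                    raise TruthError(
                        f"{mut.gene}: multiplicity {mut.multiplicity} exceeds "
                        f"copy number {total} in clone {clone.clone_id}")
                if mut.multiplicity == 2:
                    ev = self._event_at(clone.clone_id, mut.chrom, mut.pos)
                    if ev is None or ev.kind != CN_LOH:
                        raise TruthError(
                            f"{mut.gene}: multiplicity 2 requires a CN_LOH event "
                            f"carried by clone {clone.clone_id} at {mut.chrom}:{mut.pos}")

    # -- cell-population model --------------------------------------------
    def _event_at(self, clone_id: str, chrom: str, pos: int) -> Optional[CnEvent]:
        for ev in self.events:
            if clone_id in ev.clone_ids and ev.contains(chrom, pos):
                return ev
        return None

    def clone_copy_numbers(self, clone_id: str, chrom: str, pos: int) -> tuple[int, int]:
        """(B6, 129) copies at a locus in cells of one clone (diploid het if no event)."""
        ev = self._event_at(clone_id, chrom, pos)
        return (1, 1) if ev is None else ev.copy_numbers

    def populations(self, sample: str) -> list[tuple[Optional[str], float]]:
        """(clone_id or None, cell fraction) mixture for one tumor sample.

        ``None`` labels event- and mutation-free diploid cells: the admixed
        normal cells plus any tumor cells not assigned to a configured clone.
        """
        p = self.purity(sample)
        pops: list[tuple[Optional[str], float]] = []
        assigned = 0.0
        for clone in self.clones:
            w = p * clone.fraction(sample)
            if w > 0:
                pops.append((clone.clone_id, w))
            assigned += clone.fraction(sample)
        baseline = (1.0 - p) + p * max(0.0, 1.0 - assigned)
        if baseline > 1e-12:
            pops.append((None, baseline))
        return pops

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["events"] = [ev.to_dict() for ev in self.events]
        d["clones"] = [c.to_dict() for c in self.clones]
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        kwargs["events"] = tuple(
            CnEvent(**{**ev, "clone_ids": tuple(ev.get("clone_ids", ()))})
            for ev in kwargs.get("events", ()))
        kwargs["clones"] = tuple(
            CloneSpec(clone_id=c["clone_id"],
                      fraction_primary=c["fraction_primary"],
                      fraction_relapse=c["fraction_relapse"],
                      mutations=tuple(SomaticMutation(**m) for m in c.get("mutations", ())))
            for c in kwargs.get("clones", ()))
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigurationError("config YAML must be a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# expected allele fractions (exact population averages)
# ---------------------------------------------------------------------------

def expected_baf(copy_b6: float, copy_s129: float, purity: float,
                 allele: str = S129) -> float:
    """Expected strain allele fraction for tumor cells with the given copies.

    Mixture of a purity fraction of tumor cells carrying (copy_b6, copy_s129)
    haplotype copies with (1 - purity) normal cells carrying one of each:

        BAF_129 = ((1-p)*1 + p*c129) / ((1-p)*2 + p*(cB6 + c129))
    """
    if not 0.0 <= purity <= 1.0:
        raise ConfigurationError("purity must lie in [0, 1]")
    if allele not in HAPLOTYPES:
        raise ConfigurationError(f"unknown allele {allele!r}")
    num = (1.0 - purity) * 1.0 + purity * (copy_s129 if allele == S129 else copy_b6)
    den = (1.0 - purity) * 2.0 + purity * (copy_b6 + copy_s129)
    if den == 0:
        raise TruthError("total copy mass is zero; allele fraction undefined")
    return num / den


def site_expected_baf(config: SimConfig, sample: str, chrom: str, pos: int,
                      allele: str = S129) -> float:
    """Expected 129-allele fraction at an informative SNP in one tumor sample."""
    num = den = 0.0
    for clone_id, w in config.populations(sample):
        cb6, cs129 = ((1, 1) if clone_id is None
                      else config.clone_copy_numbers(clone_id, chrom, pos))
        num += w * (cs129 if allele == S129 else cb6)
        den += w * (cb6 + cs129)
    if den == 0:
        raise TruthError("total copy mass is zero; allele fraction undefined")
    return num / den


def expected_vaf(cell_fraction: float, multiplicity: int = 1,
                 tumor_copy_number: int = 2) -> float:
    """Expected somatic VAF from the same population-counting model.

    ``cell_fraction`` is the fraction of *all* cells carrying the mutation
    (purity times clone fraction); carrying cells hold ``tumor_copy_number``
    total copies of the locus, ``multiplicity`` of them mutant; all other
    cells are diploid wild-type.
    """
    if not 0.0 <= cell_fraction <= 1.0:
        raise ConfigurationError("cell_fraction must lie in [0, 1]")
    if multiplicity < 0 or multiplicity > tumor_copy_number:
        raise TruthError(
            f"multiplicity {multiplicity} exceeds local copy number {tumor_copy_number}")
    num = cell_fraction * multiplicity
    den = cell_fraction * tumor_copy_number + (1.0 - cell_fraction) * 2.0
    if den == 0:
        raise TruthError("total copy mass is zero; allele fraction undefined")
    return num / den


def site_expected_vaf(config: SimConfig, sample: str, chrom: str, pos: int,
                      gene: str) -> float:
    """Expected VAF of a configured mutation in one tumor sample.

    Unlike :func:`expected_vaf` this accounts for clones that carry a
    copy-number event at the locus without carrying the mutation.
    """
    num = den = 0.0
    found = False
    for clone_id, w in config.populations(sample):
        if clone_id is None:
            den += w * 2.0
            continue
        cb6, cs129 = config.clone_copy_numbers(clone_id, chrom, pos)
        den += w * (cb6 + cs129)
        clone = next(c for c in config.clones if c.clone_id == clone_id)
        for mut in clone.mutations:
            if mut.chrom == chrom and mut.pos == pos and mut.gene == gene:
                num += w * mut.multiplicity
                found = True
    for clone in config.clones:  # carried only by zero-fraction clones still counts as known
        if any(m.chrom == chrom and m.pos == pos and m.gene == gene
               for m in clone.mutations):
            found = True
    if not found:
        raise TruthError(f"no configured mutation {gene} at {chrom}:{pos}")
    if den == 0:
        raise TruthError("total copy mass is zero; allele fraction undefined")
    return num / den


# ---------------------------------------------------------------------------
# read-count sampling
# ---------------------------------------------------------------------------

def _draw_depths(rng: np.random.Generator, mean_depth: float, n: int,
                 overdispersion: float) -> np.ndarray:
    if overdispersion <= 0:
        return rng.poisson(mean_depth, n)
    r = 1.0 / overdispersion
    p = r / (r + mean_depth)
    return rng.negative_binomial(r, p, n)


def _observed_fraction(expected: np.ndarray, error_rate: float) -> np.ndarray:
    return expected * (1.0 - error_rate) + (1.0 - expected) * error_rate


def sample_counts(expected_fraction: float, mean_depth: float,
                  rng: np.random.Generator, error_rate: float = 0.0,
                  overdispersion: float = 0.0) -> tuple[int, int]:
    """Draw one site's (alt, ref) counts: Binomial(alt) at Poisson depth.

    A symmetric per-read error rate flips alleles before sampling.  Zero
    drawn depth yields (0, 0).
    """
    if not 0.0 <= expected_fraction <= 1.0:
        raise ConfigurationError("expected_fraction must lie in [0, 1]")
    if mean_depth <= 0:
        raise ConfigurationError("mean_depth must be positive")
    depth = int(_draw_depths(rng, mean_depth, 1, overdispersion)[0])
    if depth == 0:
        return (0, 0)
    f = float(_observed_fraction(np.asarray(expected_fraction), error_rate))
    alt = int(rng.binomial(depth, f))
    return (alt, depth - alt)


def _sample_counts_vec(expected: np.ndarray, mean_depth: float,
                       rng: np.random.Generator, error_rate: float,
                       overdispersion: float) -> tuple[np.ndarray, np.ndarray]:
    depths = _draw_depths(rng, mean_depth, expected.size, overdispersion)
    f = _observed_fraction(np.asarray(expected, dtype=float), error_rate)
    alts = rng.binomial(depths, f)
    return alts.astype(np.int64), (depths - alts).astype(np.int64)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimResult:
    """All artifacts of one simulated trio; frames feed the pipeline directly."""

    snp_primary: pd.DataFrame
    snp_relapse: pd.DataFrame
    variants: pd.DataFrame
    bins_primary: pd.DataFrame
    bins_relapse: pd.DataFrame
    truth: dict

    def truth_json(self) -> str:
        return json.dumps(self.truth, sort_keys=True, indent=1)


def _site_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Evenly spread jittered 1-based positions; sorted, unique by construction."""
    spacing = length / n
    jitter = rng.uniform(0.05, 0.95, n)
    pos = np.floor((np.arange(n) + jitter) * spacing).astype(np.int64) + 1
    return np.minimum(pos, length)


def _copy_ratio(config: SimConfig, sample: str, chrom: str, pos: int) -> float:
    """Total copy number at a locus relative to diploid, averaged over cells."""
    total = 0.0
    for clone_id, w in config.populations(sample):
        cb6, cs129 = ((1, 1) if clone_id is None
                      else config.clone_copy_numbers(clone_id, chrom, pos))
        total += w * (cb6 + cs129)
    return total / 2.0


def simulate_pair(config: SimConfig) -> SimResult:
    """Simulate matched normal + primary + relapse read-count tables.

    Returns SNP tables (one per tumor sample, each carrying the shared normal
    counts), a paired somatic-variant table, tumor/normal depth bins per
    tumor sample, and a ground-truth record.  Regeneration from the same
    config is byte-identical.
    """
    config.validate()
    seed = config.seed
    chroms = config.chromosomes
    length = config.chrom_length_bp

    # -- informative SNP sites (shared across samples) ---------------------
    sites: dict[str, dict[str, np.ndarray]] = {}
    for ci, chrom in enumerate(chroms):
        rng = _rng(seed, _ROLE_SITES, ci)
        n = max(1, int(round(config.snp_density * length / 1e6)))
        pos = _site_positions(rng, length, n)
        ref_idx = rng.integers(0, 4, n)
        alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
        sites[chrom] = {"pos": pos, "b6": _BASES[ref_idx], "s129": _BASES[alt_idx]}

    # -- SNP counts --------------------------------------------------------
    normal_counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, chrom in enumerate(chroms):
        rng = _rng(seed, _ROLE_SNP["normal"], ci)
        expected = np.full(sites[chrom]["pos"].size, 0.5)
        alt, ref = _sample_counts_vec(expected, config.mean_depth_normal, rng,
                                      config.error_rate, config.overdispersion)
        normal_counts[chrom] = (ref, alt)

    snp_frames: dict[str, pd.DataFrame] = {}
    expected_baf_truth: dict[str, dict[str, list[float]]] = {}
    for sample in TUMOR_SAMPLES:
        rows = []
        expected_baf_truth[sample] = {}
        for ci, chrom in enumerate(chroms):
            rng = _rng(seed, _ROLE_SNP[sample], ci)
            pos = sites[chrom]["pos"]
            expected = np.array([site_expected_baf(config, sample, chrom, int(p))
                                 for p in pos])
            expected_baf_truth[sample][chrom] = [round(float(e), 10) for e in expected]
            alt, ref = _sample_counts_vec(expected, config.mean_depth_tumor, rng,
                                          config.error_rate, config.overdispersion)
            nref, nalt = normal_counts[chrom]
            rows.append(pd.DataFrame({
                "chrom": chrom, "pos": pos,
                "b6_allele": sites[chrom]["b6"], "s129_allele": sites[chrom]["s129"],
                "normal_ref": nref, "normal_alt": nalt,
                "tumor_ref": ref, "tumor_alt": alt,
            }))
        snp_frames[sample] = pd.concat(rows, ignore_index=True)

    # -- somatic variants --------------------------------------------------
    mut_sites = sorted({(m.chrom, m.pos, m.gene)
                        for c in config.clones for m in c.mutations},
                       key=lambda t: (chroms.index(t[0]), t[1], t[2]))
    meta_rng = _rng(seed, _ROLE_VARIANT_META)
    var_rows = []
    expected_vaf_truth: dict[str, dict[str, float]] = {s: {} for s in TUMOR_SAMPLES}
    counts: dict[str, list[tuple[int, int]]] = {s: [] for s in ("normal", *TUMOR_SAMPLES)}
    expected_by_sample = {
        sample: np.array([site_expected_vaf(config, sample, c, p, g)
                          for c, p, g in mut_sites])
        for sample in TUMOR_SAMPLES
    } if mut_sites else {s: np.array([]) for s in TUMOR_SAMPLES}
    for sample in ("normal", *TUMOR_SAMPLES):
        rng = _rng(seed, _ROLE_VARIANT[sample])
        expected = (np.zeros(len(mut_sites)) if sample == "normal"
                    else expected_by_sample[sample])
        depth = (config.mean_depth_normal if sample == "normal"
                 else config.mean_depth_tumor)
        alt, ref = _sample_counts_vec(expected, depth, rng,
                                      config.error_rate, config.overdispersion)
        counts[sample] = list(zip(alt, alt + ref))
    for i, (chrom, pos, gene) in enumerate(mut_sites):
        ref_idx = int(meta_rng.integers(0, 4))
        alt_idx = (ref_idx + int(meta_rng.integers(1, 4))) % 4
        for sample in TUMOR_SAMPLES:
            expected_vaf_truth[sample][f"{gene}:{chrom}:{pos}"] = round(
                float(expected_by_sample[sample][i]), 10)
        var_rows.append({
            "variant_id": f"v{i + 1}_{gene}", "gene": gene, "chrom": chrom, "pos": pos,
            "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
            "normal_alt": counts["normal"][i][0], "normal_depth": counts["normal"][i][1],
            "primary_alt": counts["primary"][i][0], "primary_depth": counts["primary"][i][1],
            "relapse_alt": counts["relapse"][i][0], "relapse_depth": counts["relapse"][i][1],
        })
    variant_cols = ["variant_id", "gene", "chrom", "pos", "ref", "alt",
                    "normal_alt", "normal_depth", "primary_alt", "primary_depth",
                    "relapse_alt", "relapse_depth"]
    variants = pd.DataFrame(var_rows, columns=variant_cols)

    # -- depth bins --------------------------------------------------------
    edges = np.arange(0, length, config.bin_size_bp, dtype=np.int64)
    bin_start = edges
    bin_end = np.minimum(edges + config.bin_size_bp, length)
    normal_bins: dict[str, np.ndarray] = {}
    for ci, chrom in enumerate(chroms):
        rng = _rng(seed, _ROLE_BIN["normal"], ci)
        lam = config.mean_depth_normal * _BIN_PSEUDO_SITES
        normal_bins[chrom] = rng.poisson(lam, bin_start.size) / _BIN_PSEUDO_SITES
    bin_frames: dict[str, pd.DataFrame] = {}
    for sample in TUMOR_SAMPLES:
        rows = []
        for ci, chrom in enumerate(chroms):
            rng = _rng(seed, _ROLE_BIN[sample], ci)
            mids = (bin_start + bin_end) // 2
            ratios = np.array([_copy_ratio(config, sample, chrom, int(m)) for m in mids])
            lam = config.mean_depth_tumor * ratios * _BIN_PSEUDO_SITES
            tumor = rng.poisson(lam) / _BIN_PSEUDO_SITES
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": bin_start, "end": bin_end,
                "normal_depth": normal_bins[chrom], "tumor_depth": tumor,
            }))
        bin_frames[sample] = pd.concat(rows, ignore_index=True)

    # -- truth record ------------------------------------------------------
    truth = {
        "seed": seed,
        "config": config.to_dict(),
        "events": [ev.to_dict() for ev in config.events],
        "purity": {s: config.purity(s) for s in TUMOR_SAMPLES},
        "clone_fractions": {s: {c.clone_id: c.fraction(s) for c in config.clones}
                            for s in TUMOR_SAMPLES},
        "expected_baf": expected_baf_truth,
        "expected_vaf": expected_vaf_truth,
    }
    return SimResult(snp_primary=snp_frames["primary"],
                     snp_relapse=snp_frames["relapse"],
                     variants=variants,
                     bins_primary=bin_frames["primary"],
                     bins_relapse=bin_frames["relapse"],
                     truth=truth)
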