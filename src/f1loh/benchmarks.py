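"""Simulation-based operating characteristics of the pipeline.

Each routine regenerates synthetic data under the package's reference study
conditions (clonal events, tumor purity 0.9, ~50 informative SNPs per
chromosome, exome-scale depths) and measures how well the analysis recovers
the simulated truth.  They back both the test suite and the reproduction
script; every routine takes a ``base_seed`` so runs are reproducible.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .allelic import AllelicImbalanceCaller
from .clonal import analyze_pair, binomial_ci, detect_heterozygosity_reacquisition
from .presets import preset_config
from .simulate import CloneSpec, CnEvent, SimConfig, SomaticMutation, simulate_pair
from .types import (CN_LOH, DELETION, DE_NOVO, DEPLETED, ENRICHED, GAIN,
                    RETAINED_HET, S129, STABLE)

_MOD = 2**31


def _derive_seed(base: int, *key: int) -> int:
    h = int(base) % _MOD
    for k in key:
        h = (h * 1_000_003 + int(k) + 12345) % _MOD
    return h


def single_event_config(kind: Optional[str] = None, purity: float = 0.9,
                        depth: float = 100.0, seed: int = 0,
                        snps_per_chrom: int = 50, haplotype: str = S129,
                        mutation: Optional[SomaticMutation] = None) -> SimConfig:
    """Three-chromosome config with one clonal event (if any) spanning chr2."""
    length = snps_per_chrom * 1_000_000
    events: tuple[CnEvent, ...] = ()
    if kind is not None:
        events = (CnEvent(chrom="chr2", start=1, end=length, kind=kind,
                          haplotype=haplotype, clone_ids=("c1",)),)
    clone = CloneSpec("c1", 1.0, 1.0,
                      mutations=(mutation,) if mutation is not None else ())
    return SimConfig(seed=seed, n_chromosomes=3, chrom_length_bp=length,
                     snp_density=1.0, mean_depth_normal=depth,
                     mean_depth_tumor=depth, purity_primary=purity,
                     purity_relapse=purity, events=events, clones=(clone,),
                     bin_size_bp=2_000_000)


def classification_performance(n_seeds: int = 200, purity: float = 0.9,
                               depth: float = 100.0, snps_per_chrom: int = 50,
                               base_seed: int = 11) -> dict:
    """Per-state sensitivity/specificity of whole-chromosome classification.

    For each seed and each condition (clonal CN-LOH, hemizygous deletion, or
    no event on chr2; chr1/chr3 always retained-het), the caller is fit on
    the simulated primary sample and every chromosome's predicted state is
    scored against the simulated truth.
    """
    conditions = {CN_LOH: CN_LOH, DELETION: DELETION, RETAINED_HET: None}
    tp: dict[str, int] = {}
    fn: dict[str, int] = {}
    fp: dict[str, int] = {}
    tn: dict[str, int] = {}
    states = (CN_LOH, DELETION, RETAINED_HET)
    for s in states:
        tp[s] = fn[s] = fp[s] = tn[s] = 0
    for i in range(n_seeds):
        for ci, (label, kind) in enumerate(conditions.items()):
            config = single_event_config(kind=kind, purity=purity, depth=depth,
                                         seed=_derive_seed(base_seed, i, ci),
                                         snps_per_chrom=snps_per_chrom)
            result = simulate_pair(config)
            caller = AllelicImbalanceCaller().fit(result.snp_primary,
                                                  result.bins_primary)
            predicted = {s.chrom: s.state for s in caller.segments_}
            truth = {"chr1": RETAINED_HET, "chr2": label, "chr3": RETAINED_HET}
            for chrom, true_state in truth.items():
                pred = predicted[chrom]
                for s in states:
                    if true_state == s and pred == s:
                        tp[s] += 1
                    elif true_state == s:
                        fn[s] += 1
                    elif pred == s:
                        fp[s] += 1
                    else:
                        tn[s] += 1
    sensitivity = {s: tp[s] / (tp[s] + fn[s]) for s in states}
    specificity = {s: tn[s] / (tn[s] + fp[s]) for s in states}
    return {"sensitivity": sensitivity, "specificity": specificity,
            "n_seeds": n_seeds}


def duplication_call_rates(n_seeds: int = 200, purity: float = 0.9,
                           depth: float = 140.0, base_seed: int = 23) -> dict:
    """Mutant-duplication call rates for a true duplication vs a het control.

    The true case is a clonal multiplicity-2 mutation inside chromosome-wide
    CN-LOH (expected VAF = purity); the control is the same mutation at
    multiplicity 1 on a diploid background (expected VAF = purity / 2).
    """
    mid = 25_000_000
    called_dup = called_het = 0
    for i in range(n_seeds):
        cfg_dup = single_event_config(
            kind=CN_LOH, purity=purity, depth=depth,
            seed=_derive_seed(base_seed, i, 0),
            mutation=SomaticMutation("chr2", mid, "Kras", multiplicity=2))
        cfg_het = single_event_config(
            kind=None, purity=purity, depth=depth,
            seed=_derive_seed(base_seed, i, 1),
            mutation=SomaticMutation("chr2", mid, "Kras", multiplicity=1))
        for cfg, counter in ((cfg_dup, "dup"), (cfg_het, "het")):
            result = simulate_pair(cfg)
            caller = AllelicImbalanceCaller().fit(result.snp_primary,
                                                  result.bins_primary)
            calls = caller.call_duplications(result.variants, sample="primary")
            if calls[0].duplicated:
                if counter == "dup":
                    called_dup += 1
                else:
                    called_het += 1
    return {"true_duplication_call_rate": called_dup / n_seeds,
            "het_false_call_rate": called_het / n_seeds,
            "n_seeds": n_seeds}


def clonal_dynamics_rates(preset_name: str, n_seeds: int = 100,
                          base_seed: int = 37) -> dict:
    """Recovery rates of the preset's expected clonal-evolution narrative.

    For the 73m-like preset: the duplicated driver (Kras) must come out
    DEPLETED, the resistance mutation (Pten) ENRICHED, and driver
    heterozygosity re-acquisition must be detected.  For jw81-like: the
    resistance mutation must come out DE_NOVO.
    """
    n_dep = n_enr = n_reacq = n_denovo = 0
    for i in range(n_seeds):
        config = preset_config(preset_name, seed=_derive_seed(base_seed, i))
        result = simulate_pair(config)
        table = analyze_pair(result.variants)
        by_gene = table.set_index(result.variants["gene"].values)
        if preset_name == "73m-like":
            n_dep += by_gene.loc["Kras", "status"] == DEPLETED
            n_enr += by_gene.loc["Pten", "status"] == ENRICHED
            caller = AllelicImbalanceCaller().fit(result.snp_primary,
                                                  result.bins_primary)
            calls = caller.call_duplications(result.variants, sample="primary")
            kras_call = next(c for c in calls if "Kras" in c.variant_id)
            row = result.variants[result.variants["gene"] == "Kras"].iloc[0]
            n_reacq += detect_heterozygosity_reacquisition(
                kras_call, int(row["relapse_alt"]), int(row["relapse_depth"]))
        else:
            n_denovo += by_gene.loc["Pten", "status"] == DE_NOVO
    out: dict = {"n_seeds": n_seeds}
    if preset_name == "73m-like":
        out.update(driver_depleted_rate=n_dep / n_seeds,
                   resistance_enriched_rate=n_enr / n_seeds,
                   het_reacquired_rate=n_reacq / n_seeds)
    else:
        out.update(de_novo_rate=n_denovo / n_seeds)
    return out


def _null_config(seed: int, depth: float = 140.0,
                 n_variants: int = 20) -> SimConfig:
    """Identical clone structure in both samples: every VAF shift is noise."""
    length = 50_000_000
    genes = [f"g{i:02d}" for i in range(n_variants)]
    muts_a = tuple(SomaticMutation("chr1", 2_000_000 + i * 2_300_000, genes[i])
                   for i in range(n_variants // 2))
    muts_b = tuple(SomaticMutation("chr2", 2_000_000 + i * 2_300_000,
                                   genes[i + n_variants // 2])
                   for i in range(n_variants - n_variants // 2))
    clones = (CloneSpec("major", 0.55, 0.55, mutations=muts_a),
              CloneSpec("minor", 0.30, 0.30, mutations=muts_b))
    return SimConfig(seed=seed, n_chromosomes=3, chrom_length_bp=length,
                     snp_density=1.0, mean_depth_normal=depth,
                     mean_depth_tumor=depth, purity_primary=0.9,
                     purity_relapse=0.9, clones=clones, bin_size_bp=2_000_000)


def type_one_error(n_seeds: int = 200, alpha: float = 0.05,
                   base_seed: int = 53) -> dict:
    """Fraction of non-STABLE calls on null primary/relapse pairs."""
    n_calls = n_nonstable = 0
    for i in range(n_seeds):
        config = _null_config(_derive_seed(base_seed, i))
        result = simulate_pair(config)
        table = analyze_pair(result.variants, alpha=alpha)
        n_calls += len(table)
        n_nonstable += int((table["status"] != STABLE).sum())
    return {"nonstable_fraction": n_nonstable / n_calls,
            "n_calls": n_calls, "n_seeds": n_seeds}


def clopper_pearson_coverage(n: int = 100, p: float = 0.3,
                             n_draws: int = 10_000, confidence: float = 0.95,
                             base_seed: int = 7) -> dict:
    """Empirical coverage of the exact binomial interval at (n, p)."""
    rng = np.random.default_rng(_derive_seed(base_seed))
    bounds = np.array([binomial_ci(k, n, confidence) for k in range(n + 1)])
    ks = rng.binomial(n, p, n_draws)
    covered = (bounds[ks, 0] <= p) & (p <= bounds[ks, 1])
    return {"coverage": float(covered.mean()), "n_draws": n_draws}


def purity_recovery(purities: tuple[float, ...] = (0.7, 0.8, 0.9, 0.95),
                    n_seeds: int = 50, depth: float = 100.0,
                    base_seed: int = 61) -> dict:
    """Error of the BAF-implied purity (2*folded - 1) on clonal CN-LOH.

    Estimated from the chr2 folded-BAF mean directly, which is what the
    CN-LOH purity estimate inverts.
    """
    errors = []
    for pi, purity in enumerate(purities):
        for i in range(n_seeds):
            config = single_event_config(kind=CN_LOH, purity=purity, depth=depth,
                                         seed=_derive_seed(base_seed, pi, i))
            result = simulate_pair(config)
            caller = AllelicImbalanceCaller().fit(result.snp_primary,
                                                  result.bins_primary)
            seg = next(s for s in caller.segments_ if s.chrom == "chr2")
            estimate = 2.0 * seg.mean_folded_baf - 1.0
            errors.append(abs(estimate - purity))
    errors = np.asarray(errors)
    return {"max_abs_error": float(errors.max()),
            "mean_abs_error": float(errors.mean()),
            "n": errors.size}
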