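"""Cohort-level mutation burden and pathway recurrence summaries."""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .errors import ConfigurationError, FormatError

UNMAPPED = "unmapped"


@dataclasses.dataclass(frozen=True)
class BurdenSummary:
    """Somatic alteration burden of one sample over the callable target."""

    sample_id: str
    n_somatic: int
    target_mb: float

    @property
    def per_mb(self) -> float:
        return mutation_burden(self.n_somatic, self.target_mb)


def mutation_burden(n_somatic: int, target_mb: float) -> float:
    """Somatic alterations per megabase of callable exome: n / target_mb."""
    if target_mb <= 0:
        raise ConfigurationError("target_mb must be positive")
    if n_somatic < 0:
        raise ValueError("n_somatic must be non-negative")
    return n_somatic / target_mb


def burden_table(counts: Mapping[str, int], target_mb: float) -> pd.DataFrame:
    """Per-sample burden table from a {sample: somatic count} mapping."""
    rows = [{"sample": s, "n_somatic": int(n), "target_mb": target_mb,
             "burden_per_mb": mutation_burden(int(n), target_mb)}
            for s, n in counts.items()]
    return pd.DataFrame(rows, columns=["sample", "n_somatic", "target_mb",
                                       "burden_per_mb"])


def read_pathway_map(path: Union[str, Path]) -> dict[str, str]:
    """Gene-to-pathway map from a two-column TSV (gene, pathway)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "pathway"} <= set(df.columns):
        raise FormatError(f"{path}: need columns gene, pathway")
    mapping: dict[str, str] = {}
    for i, r in enumerate(df.itertuples(index=False)):
        gene, pathway = str(r.gene), str(r.pathway)
        if gene in mapping and mapping[gene] != pathway:
            raise FormatError(
                f"{path} line {i + 2}: gene {gene} mapped to both "
                f"{mapping[gene]} and {pathway}")
        mapping[gene] = pathway
    return mapping


def pathway_recurrence(alterations: pd.DataFrame,
                       pathway_map: Mapping[str, str],
                       total_samples: Optional[int] = None) -> pd.DataFrame:
    """Per-pathway recurrence across a cohort of alteration calls.

    ``alterations`` needs columns ``sample`` and ``gene`` (alteration class
    is irrelevant to the tally: insertions, SNVs, indels and copy losses all
    count).  A sample counts at most once per pathway however many member
    genes are hit; genes absent from the map are tallied under "unmapped",
    never dropped.  ``total_samples`` defaults to the number of distinct
    samples in the table (pass the cohort size when some samples are clean).
    """
    if not {"sample", "gene"} <= set(alterations.columns):
        raise FormatError("alterations table needs columns sample, gene")
    df = alterations[["sample", "gene"]].drop_duplicates().copy()
    n_total = int(total_samples) if total_samples is not None else df["sample"].nunique()
    if n_total <= 0:
        raise ConfigurationError("total_samples must be positive")
    df["pathway"] = [pathway_map.get(g, UNMAPPED) for g in df["gene"].astype(str)]
    hits = df[["sample", "pathway"]].drop_duplicates()
    pathways = sorted(set(pathway_map.values()) | set(hits["pathway"]))
    rows = []
    for pw in pathways:
        n = int((hits["pathway"] == pw).sum())
        rows.append({"pathway": pw, "n_samples": n, "fraction": n / n_total})
    out = pd.DataFrame(rows, columns=["pathway", "n_samples", "fraction"])
    return out.sort_values(["n_samples", "pathway"],
                           ascending=[False, True]).reset_index(drop=True)
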