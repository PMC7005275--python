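"""Count normalization and log2 fold-changes versus the plasmid-DNA pool.

Raw guide counts are normalized to reads per million within each condition,
a pseudocount of one is added, and the result is log2-transformed:

    norm(g, c) = log2( count(g, c) / total(c) * 1e6 + 1 )

The pseudocount is applied after RPM scaling (not to the raw counts), so a
guide with zero reads maps exactly to 0.  The log2 fold-change of guide g in
condition c is then norm(g, c) − norm(g, pDNA), where the pDNA column is the
sequenced library plasmid pool that sets the initial abundance baseline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


def lognorm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(reads-per-million + 1) within each condition column."""
    totals = counts.sum(axis=0)
    zero_total = totals[totals <= 0]
    if len(zero_total):
        raise ValueError(
            f"conditions with zero total reads: {', '.join(map(str, zero_total.index))}"
        )
    rpm = counts / totals * 1e6
    return np.log2(rpm + 1.0)


def compute_lfc(norm: pd.DataFrame, reference_condition: str) -> pd.DataFrame:
    """Per-guide log2 fold-change of every non-reference column vs pDNA."""
    if reference_condition not in norm.columns:
        raise ValueError(f"reference condition {reference_condition!r} not in matrix")
    others = [c for c in norm.columns if c != reference_condition]
    lfc = norm[others].sub(norm[reference_condition], axis=0)
    lfc.index.name = "guide_id"
    return lfc


def average_replicates(
    lfcs: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean of replicate LFC columns within each screen arm.

    ``grouping`` maps every replicate column of ``lfcs`` to an arm label;
    the returned table has one column per arm.
    """
    missing = [c for c in lfcs.columns if c not in grouping]
    if missing:
        raise ValueError(f"replicates not assigned to an arm: {missing}")
    arms: dict[str, list[str]] = {}
    for rep, arm in grouping.items():
        if rep in lfcs.columns:
            arms.setdefault(arm, []).append(rep)
    empty = [arm for arm, reps in arms.items() if not reps]
    if empty or not arms:
        raise ValueError(f"arms with zero replicates: {empty or list(grouping.values())}")
    out = pd.DataFrame(
        {arm: lfcs[reps].mean(axis=1) for arm, reps in arms.items()},
        index=lfcs.index,
    )
    out.index.name = "guide_id"
    return out


def flag_zero_reference_guides(
    counts: pd.DataFrame, reference_condition: str
) -> pd.Index:
    """Guides with zero reads in the pDNA reference (finite LFC only via the
    pseudocount); returned for reporting, filtering is the caller's choice."""
    return counts.index[counts[reference_condition] == 0]


def replicate_correlation(lfcs: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of LFCs between replicate columns (QC)."""
    return lfcs.corr(method="pearson")


def lfc_pipeline(
    counts: pd.DataFrame,
    reference_condition: str,
    grouping: Mapping[str, str] | None = None,
    drop_zero_reference: bool = False,
) -> pd.DataFrame:
    """Counts -> normalized -> LFC vs pDNA -> optional replicate averaging."""
    if drop_zero_reference:
        flagged = flag_zero_reference_guides(counts, reference_condition)
        counts = counts.drop(index=flagged)
    lfc = compute_lfc(lognorm(counts), reference_condition)
    if grouping is not None:
        lfc = average_replicates(lfc, grouping)
    return lfc


def write_lfc_table(lfc: pd.DataFrame, path: str | Path) -> None:
    lfc.to_csv(path, sep="\t")


def read_lfc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "guide_id"
    return df
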