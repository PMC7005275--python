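"""Gene-set benchmarking with a one-sided two-sample KS statistic.

For a benchmark set S and per-gene Z-scores, the statistic is

    D+ = sup_x [ F_in(x) − F_out(x) ]

where F_in and F_out are the empirical CDFs of Z for genes in and not in S.
A set shifted toward negative Z (sensitizers / synthetic-lethal partners)
gives a large D+.  The one-sided p-value uses the asymptotic approximation
exp(−2 D+² m n / (m+n)), which is set-size dependent — D+ itself is the
comparable quantity across sets of different sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    ks_stat: float
    p_one_sided: float
    n_in: int
    n_out: int


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> source <tab> member...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(name=fields[0], source=fields[1], members=frozenset(fields[2:])))
    return sets


def ks_one_sided(in_values: np.ndarray, out_values: np.ndarray) -> tuple[float, float]:
    """D+ = sup_x [F_in(x) − F_out(x)] and its asymptotic one-sided p."""
    in_values = np.sort(np.asarray(in_values, dtype=float))
    out_values = np.sort(np.asarray(out_values, dtype=float))
    m, n = len(in_values), len(out_values)
    # evaluate at all observed breakpoints; the sup of a right-continuous
    # step-function difference is attained at a data point
    grid = np.concatenate([in_values, out_values])
    f_in = np.searchsorted(in_values, grid, side="right") / m
    f_out = np.searchsorted(out_values, grid, side="right") / n
    d_plus = float(max(np.max(f_in - f_out), 0.0))
    p = float(min(1.0, np.exp(-2.0 * d_plus**2 * m * n / (m + n))))
    return d_plus, p


def ks_enrichment(
    scores: Mapping[str, float] | pd.Series,
    gene_set: GeneSet,
    alternative: str = "sensitizer",
) -> EnrichmentResult:
    """One-sided KS enrichment of a gene set in a Z-score profile.

    ``alternative='sensitizer'`` (default) tests whether the in-set CDF lies
    above the out-set CDF, i.e. the set is shifted toward negative Z;
    ``'resistance'`` flips the direction.
    """
    scores = pd.Series(scores, dtype=float)
    in_mask = scores.index.isin(gene_set.members)
    n_in = int(in_mask.sum())
    n_out = int(len(scores) - n_in)
    dropped = len(gene_set.members) - n_in
    if dropped:
        logger.info("gene set %s: %d members absent from the scored universe", gene_set.name, dropped)
    if n_in == 0 or n_out == 0:
        raise ValueError(
            f"gene set {gene_set.name!r}: degenerate partition of the scored universe "
            f"(n_in={n_in}, n_out={n_out})"
        )
    in_z = scores[in_mask].to_numpy()
    out_z = scores[~in_mask].to_numpy()
    if alternative == "resistance":
        in_z, out_z = -in_z, -out_z
    elif alternative != "sensitizer":
        raise ValueError(f"unknown alternative {alternative!r}")
    d_plus, p = ks_one_sided(in_z, out_z)
    return EnrichmentResult(gene_set.name, d_plus, p, n_in, n_out)


def enrichment_panel(
    score_tables: Mapping[str, Mapping[str, float] | pd.Series],
    gene_sets: Sequence[GeneSet],
    alternative: str = "sensitizer",
) -> pd.DataFrame:
    """One KS result per (condition, gene set) pair.

    Returns a long-format frame with columns condition, set_name, ks_stat,
    p_one_sided, n_in, n_out.
    """
    rows = []
    for condition, scores in score_tables.items():
        for gs in gene_sets:
            res = ks_enrichment(scores, gs, alternative=alternative)
            rows.append(
                {
                    "condition": condition,
                    "set_name": res.set_name,
                    "ks_stat": res.ks_stat,
                    "p_one_sided": res.p_one_sided,
                    "n_in": res.n_in,
                    "n_out": res.n_out,
                }
            )
    return pd.DataFrame(rows)
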