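"""Genetic-interaction scoring by spline residuals and gene-level Z-scores.

The fitness effect of knocking out gene B in an anchor-perturbed population
is compared with its effect in a control population by regressing the
perturbed-arm guide LFCs on the control-arm guide LFCs with a natural cubic
spline (three degrees of freedom plus intercept).  The spline absorbs the
shared, possibly nonlinear, fitness trend; the residual of each guide from
the fit is its interaction phenotype.  A positive residual is a buffering
interaction (the guide drops out less than expected in the anchor
background), a negative residual a synthetic-lethal one.

Guide residuals are aggregated per gene as

    Z(gene) = ( mean residual of the gene's guides − mean of all residuals )
              / ( sd of all residuals / sqrt(n_guides) )

with the sample (n−1) standard deviation, assuming residuals are
approximately normal and the all-guide mean and sd represent the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# Natural cubic spline basis and least-squares fit
# --------------------------------------------------------------------------

def natural_spline_basis(
    x: np.ndarray, knots: np.ndarray
) -> np.ndarray:
    """Natural cubic spline basis (truncated-power construction, no intercept).

    ``knots`` holds boundary and interior knots in increasing order; with K
    knots the basis has K−1 columns and the span contains all cubic splines
    with those knots that are linear beyond the boundary knots (which
    includes every affine function of x).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    if K < 2:
        raise ValueError("need at least two knots (the boundary)")

    def d(k: int) -> np.ndarray:
        # divided difference of truncated cubics against the last knot
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    if K >= 3:
        d_last = d(K - 2)
        cols.extend(d(k) - d_last for k in range(K - 2))
    return np.column_stack(cols)


def spline_knots(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Boundary knots at min/max of x, df−1 interior knots at equally
    spaced quantiles."""
    x = np.asarray(x, dtype=float)
    n_interior = df - 1
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    interior = np.quantile(x, probs)
    knots = np.concatenate([[x.min()], interior, [x.max()]])
    if np.unique(knots).size != knots.size:
        raise ValueError("degenerate x: duplicated knots (too little spread)")
    return knots


@dataclass(frozen=True)
class SplineModel:
    """Fitted natural-cubic-spline regression of perturbed on control LFCs."""

    knots: np.ndarray
    coefficients: np.ndarray  # [intercept, basis coefficients...]
    df: int

    def design(self, x: np.ndarray) -> np.ndarray:
        basis = natural_spline_basis(x, self.knots)
        return np.column_stack([np.ones(len(basis)), basis])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.design(np.asarray(x, dtype=float)) @ self.coefficients


def fit_spline(x: np.ndarray, y: np.ndarray, df: int = 3) -> SplineModel:
    """Least-squares natural-spline fit of y (perturbed LFC) on x (control LFC)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: x has {x.size}, y has {y.size}")
    if x.size < 10:
        raise ValueError("need at least 10 observations to fit the spline")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all control-arm LFCs identical")
    knots = spline_knots(x, df=df)
    design = np.column_stack([np.ones(x.size), natural_spline_basis(x, knots)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return SplineModel(knots=knots, coefficients=coef, df=df)


def guide_residuals(
    model: SplineModel,
    x: np.ndarray,
    y: np.ndarray,
    guide_ids: Sequence[str],
) -> pd.Series:
    """Observed minus spline-predicted perturbed-arm LFC, per guide."""
    resid = np.asarray(y, dtype=float) - model.predict(x)
    return pd.Series(resid, index=pd.Index(guide_ids, name="guide_id"), name="residual")


# --------------------------------------------------------------------------
# Gene-level aggregation
# --------------------------------------------------------------------------

def gene_z(residuals: pd.Series, guide_map: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate guide residuals to per-gene Z-scores.

    Returns a frame indexed by gene_symbol with columns n_guides,
    mean_residual and z.  Raises on unmapped guides or a degenerate screen
    (zero residual spread).
    """
    unmapped = [g for g in residuals.index if g not in guide_map]
    if unmapped:
        raise ValueError(f"guides without a gene mapping: {unmapped[:5]}...")
    global_mean = float(residuals.mean())
    global_sd = float(residuals.std(ddof=1))
    if not np.isfinite(global_sd) or global_sd == 0:
        raise ValueError("degenerate screen: all guide residuals identical")
    genes = residuals.index.map(guide_map)
    grouped = residuals.groupby(genes)
    out = pd.DataFrame(
        {
            "n_guides": grouped.size(),
            "mean_residual": grouped.mean(),
        }
    )
    out["z"] = (out["mean_residual"] - global_mean) / (
        global_sd / np.sqrt(out["n_guides"])
    )
    out.index.name = "gene_symbol"
    return out


def rank_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Add ascending (1 = most synthetic-lethal) and descending (1 = most
    buffering) ranks; ties broken by gene symbol for determinism."""
    out = scores.copy()
    order = out.reset_index().sort_values(
        ["z", "gene_symbol"], ascending=[True, True]
    )["gene_symbol"]
    asc = pd.Series(np.arange(1, len(order) + 1), index=order)
    order_desc = out.reset_index().sort_values(
        ["z", "gene_symbol"], ascending=[False, True]
    )["gene_symbol"]
    desc = pd.Series(np.arange(1, len(order_desc) + 1), index=order_desc)
    out["rank_ascending"] = asc.reindex(out.index).astype(int)
    out["rank_descending"] = desc.reindex(out.index).astype(int)
    return out


def combine_conditions(
    per_condition_scores: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Average per-gene Z across a named list of screen conditions.

    Genes missing from a condition are excluded from that condition's
    contribution (not imputed); the result is re-ranked by |avg_z|.
    """
    if not per_condition_scores:
        raise ValueError("no conditions to combine")
    zs = pd.DataFrame({name: df["z"] for name, df in per_condition_scores.items()})
    out = pd.DataFrame({"avg_z": zs.mean(axis=1, skipna=True)})
    out["n_conditions"] = zs.notna().sum(axis=1)
    out = out.sort_values("avg_z", key=lambda s: -s.abs(), kind="mergesort")
    out["rank_abs"] = np.arange(1, len(out) + 1)
    out.index.name = "gene_symbol"
    return out


def score_condition(
    lfc: pd.DataFrame,
    control_arm: str,
    perturbed_arm: str,
    guide_map: Mapping[str, str],
    df: int = 3,
) -> pd.DataFrame:
    """Full scoring of one perturbed arm against its control arm."""
    x = lfc[control_arm].to_numpy()
    y = lfc[perturbed_arm].to_numpy()
    model = fit_spline(x, y, df=df)
    resid = guide_residuals(model, x, y, lfc.index)
    return rank_scores(gene_z(resid, guide_map))
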