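"""Synthetic pooled anchor screens with ground truth.

The generator emulates the structure of a genome-wide anchor screen run
with a Brunello-like library (four guides per gene): guide abundance in the
plasmid pool is lognormal; over the screen each guide's expected abundance
changes by 2^(e_i * f_g) in the control arm and 2^(e_i * (f_g + delta_g))
in the anchor arm, where f_g <= 0 is the gene's fitness effect (log2 units
over the screen), delta_g the anchor-dependent interaction shift (negative
= synthetic lethal, positive = buffering) and e_i in [0, 1] the guide's
efficacy; replicate read counts are negative-binomial around the expected
reads-per-guide at the configured sequencing depth.  Every planted quantity
is returned as ground truth so downstream recovery is checkable.

Also provided: a FASTQ emitter that inverts read counting (for
deconvolution round-trips), the knockout-dilution growth model motivating
simultaneous anchor/library editing, and a factor-model co-essentiality
matrix generator for network tests.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .deconvolution import BarcodeMap, GuideReference

_BASES = "ACGT"


# --------------------------------------------------------------------------
# Configuration and ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one anchor screen.

    Defaults describe a desk-scale screen with the structure of the real
    ones: 4 guides/gene, two biological replicates per arm, lognormal
    plasmid abundance, ~10% of genes with a fitness cost, 5% of genes
    carrying an interaction of magnitude 1 (log2 units, half buffering /
    half synthetic lethal), high-efficacy guides, 500 reads/guide depth and
    mild negative-binomial overdispersion.
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    fitness_fraction: float = 0.10
    fitness_shape: float = 2.0        # gamma shape of |f_g|
    fitness_scale: float = 0.5        # gamma scale of |f_g| (mean = shape*scale)
    interaction_fraction: float = 0.05
    interaction_magnitude: float = 1.0
    buffering_fraction: float = 0.5   # of interacting genes, delta > 0
    efficacy_alpha: float = 5.0       # beta-distribution parameters of e_i
    efficacy_beta: float = 1.0
    pdna_sigma: float = 0.5           # lognormal log-sd of plasmid abundance
    depth_per_guide: float = 500.0    # mean sequenced reads per guide
    dispersion: float = 0.05          # NB: var = mu + dispersion * mu^2; 0 = Poisson
    replicates: int = 2
    anchor_efficiency: float = 1.0    # fraction of anchor-arm cells actually edited
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.guides_per_gene < 1:
            problems.append("guides_per_gene must be >= 1")
        for name in ("fitness_fraction", "interaction_fraction",
                     "buffering_fraction", "anchor_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if self.depth_per_guide <= 0:
            problems.append("depth_per_guide must be > 0")
        if self.dispersion < 0:
            problems.append("dispersion must be >= 0")
        if self.pdna_sigma < 0:
            problems.append("pdna_sigma must be >= 0")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if self.efficacy_alpha <= 0 or self.efficacy_beta <= 0:
            problems.append("efficacy beta-distribution parameters must be > 0")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters: per-gene fitness/interaction and per-guide efficacy."""

    genes: pd.DataFrame   # index gene_symbol; fitness, delta, label
    guides: pd.DataFrame  # index guide_id; gene_symbol, efficacy

    @property
    def guide_map(self) -> dict[str, str]:
        return self.guides["gene_symbol"].to_dict()

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.genes.index[self.genes["label"] == label])


# --------------------------------------------------------------------------
# Screen simulation
# --------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion*mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_screen(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a pDNA + control-arm + anchor-arm count matrix.

    Columns: ``pDNA``, ``control_rep{1..R}``, ``anchor_rep{1..R}``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes, gpg = config.n_genes, config.guides_per_gene
    n_guides = n_genes * gpg

    width = max(4, len(str(n_genes)))
    gene_symbols = np.array([f"GENE{i + 1:0{width}d}" for i in range(n_genes)])
    guide_genes = np.repeat(gene_symbols, gpg)
    guide_ids = np.array(
        [f"{g}_sg{i % gpg + 1}" for i, g in enumerate(guide_genes)]
    )

    # per-gene fitness f_g <= 0
    fitness = np.zeros(n_genes)
    n_fit = int(round(config.fitness_fraction * n_genes))
    fit_idx = rng.choice(n_genes, size=n_fit, replace=False)
    fitness[fit_idx] = -rng.gamma(config.fitness_shape, config.fitness_scale, size=n_fit)

    # per-gene interaction delta_g, planted independently of fitness status
    delta = np.zeros(n_genes)
    n_int = int(round(config.interaction_fraction * n_genes))
    int_idx = rng.choice(n_genes, size=n_int, replace=False)
    n_buf = int(round(config.buffering_fraction * n_int))
    signs = np.concatenate([np.ones(n_buf), -np.ones(n_int - n_buf)])
    delta[int_idx] = signs * config.interaction_magnitude
    label = np.where(delta > 0, "buffering", np.where(delta < 0, "synthetic_lethal", "null"))

    efficacy = rng.beta(config.efficacy_alpha, config.efficacy_beta, size=n_guides)

    # plasmid pool abundance, lognormal, scaled to the sequencing depth
    pdna_abund = rng.lognormal(mean=0.0, sigma=config.pdna_sigma, size=n_guides)
    depth_total = config.depth_per_guide * n_guides

    f_guide = np.repeat(fitness, gpg)
    d_guide = np.repeat(delta, gpg)
    w = config.anchor_efficiency
    control_abund = pdna_abund * 2.0 ** (efficacy * f_guide)
    anchor_abund = pdna_abund * (
        w * 2.0 ** (efficacy * (f_guide + d_guide))
        + (1.0 - w) * 2.0 ** (efficacy * f_guide)
    )

    columns: dict[str, np.ndarray] = {}
    columns["pDNA"] = _nb_counts(
        rng, pdna_abund / pdna_abund.sum() * depth_total, config.dispersion
    )
    for arm, abund in (("control", control_abund), ("anchor", anchor_abund)):
        mu = abund / abund.sum() * depth_total
        for rep in range(1, config.replicates + 1):
            columns[f"{arm}_rep{rep}"] = _nb_counts(rng, mu, config.dispersion)

    counts = pd.DataFrame(columns, index=pd.Index(guide_ids, name="guide_id"))
    truth = GroundTruth(
        genes=pd.DataFrame(
            {"fitness": fitness, "delta": delta, "label": label},
            index=pd.Index(gene_symbols, name="gene_symbol"),
        ),
        guides=pd.DataFrame(
            {"gene_symbol": guide_genes, "efficacy": efficacy},
            index=pd.Index(guide_ids, name="guide_id"),
        ),
    )
    return counts, truth


def replicate_grouping(counts: pd.DataFrame) -> dict[str, str]:
    """Map ``{arm}_rep{k}`` columns to their arm label (pDNA excluded)."""
    return {
        c: c.rsplit("_rep", 1)[0] for c in counts.columns if "_rep" in c
    }


# --------------------------------------------------------------------------
# Guide reference, barcodes, FASTQ emission
# --------------------------------------------------------------------------

def _random_unique_spacers(rng: np.random.Generator, n: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        spacer = "".join(_BASES[b] for b in rng.integers(0, 4, size=20))
        if spacer not in seen:
            seen.add(spacer)
            out.append(spacer)
    return out


def simulate_reference(
    guide_ids: Sequence[str],
    guide_map: dict[str, str],
    seed: int = 0,
    library_name: str = "synthetic",
) -> GuideReference:
    """Random unique 20-nt spacers for a set of guides."""
    rng = np.random.default_rng(seed)
    spacers = _random_unique_spacers(rng, len(guide_ids))
    return GuideReference(
        guide_ids=tuple(guide_ids),
        spacers=tuple(spacers),
        gene_symbols=tuple(guide_map[g] for g in guide_ids),
        library_name=library_name,
    )


def simulate_barcodes(conditions: Sequence[str], seed: int = 0) -> BarcodeMap:
    """Distinct random 8-nt barcodes, one per condition."""
    rng = np.random.default_rng(seed)
    barcodes: dict[str, str] = {}
    for cond in conditions:
        while True:
            bc = "".join(_BASES[b] for b in rng.integers(0, 4, size=8))
            if bc not in barcodes:
                barcodes[bc] = cond
                break
    return BarcodeMap(barcodes)


def simulate_fastq(
    counts: pd.DataFrame,
    reference: GuideReference,
    barcodes: BarcodeMap,
    flank: tuple[str, str] = ("TATCTTGTGGAAAGGACGAAA", "GTTTTAGAGCTAGAAATAGCAAG"),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Emit exactly count(g, c) reads per cell, shuffled.

    Each read is ``flank[0] + 'CACCG' + spacer(g) + flank[1]`` paired with
    the barcode of condition c.  Inverse of ``count_reads`` by construction.
    """
    spacer_of = dict(zip(reference.guide_ids, reference.spacers))
    missing = [g for g in counts.index if g not in spacer_of]
    if missing:
        raise ValueError(f"guides missing from the reference: {missing[:5]}")
    cond_barcode = {c: bc for bc, c in barcodes.barcode_to_condition.items()}
    unknown = [c for c in counts.columns if c not in cond_barcode]
    if unknown:
        raise ValueError(f"conditions without a barcode: {unknown}")

    reads: list[tuple[str, str]] = []
    for cond in counts.columns:
        bc = cond_barcode[cond]
        col = counts[cond]
        for guide_id, n in col.items():
            seq = flank[0] + "CACCG" + spacer_of[guide_id] + flank[1]
            reads.extend([(seq, bc)] * int(n))
    rng = np.random.default_rng(seed)
    rng.shuffle(reads)
    return reads


def write_fastq(
    reads: Sequence[tuple[str, str]], path: str | Path, quality_char: str = "I"
) -> None:
    """Write (sequence, barcode) reads as FASTQ (gzipped if path ends .gz);
    the barcode goes in the header comment, where ``read_fastq_reads``
    recovers it."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, (seq, bc) in enumerate(reads):
            fh.write(f"@read{i} {bc}\n{seq}\n+\n{quality_char * len(seq)}\n")


# --------------------------------------------------------------------------
# Knockout-dilution growth model
# --------------------------------------------------------------------------

def knockout_fraction(
    f0: float, relative_rate: float, t_days: float, doubling_time_wt: float = 1.0
) -> float:
    """Fraction of knockout cells after t days of competitive growth.

    Wild-type cells double every ``doubling_time_wt`` days; knockout cells
    grow at ``relative_rate`` times the wild-type rate.  With a 90% initial
    knockout pool growing 20% slower, the knockouts fall below half of the
    population within three weeks — the reason anchor editing is triggered
    together with the library rather than before expansion.
    """
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("f0 must be in [0, 1]")
    if relative_rate < 0 or t_days < 0:
        raise ValueError("relative_rate and t_days must be >= 0")
    doublings = t_days / doubling_time_wt
    ko = f0 * 2.0 ** (relative_rate * doublings)
    wt = (1.0 - f0) * 2.0 ** doublings
    return ko / (ko + wt)


# --------------------------------------------------------------------------
# Planted co-essentiality structure
# --------------------------------------------------------------------------

def simulate_coessentiality(
    n_genes: int,
    planted_blocks: Sequence[tuple[Sequence[int], float]] = (),
    background_sd: float = 0.0,
    seed: int = 0,
    gene_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene-by-gene correlation matrix with planted correlated blocks.

    A one-factor-per-block model: genes in a block load sqrt(r) on a shared
    factor, so within-block correlation is exactly r and off-block exactly 0.
    ``background_sd`` adds sampling noise by drawing N = ceil(1/sd^2)
    profiles from the model and returning their sample correlation (sd ~
    1/sqrt(N) on null entries); 0 returns the exact model matrix, which is
    the identity when no blocks are planted.
    """
    if gene_names is None:
        gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    seen: set[int] = set()
    for members, r in planted_blocks:
        if not 0.0 <= r < 1.0:
            raise ValueError(f"block correlation must be in [0, 1), got {r}")
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"overlapping blocks at gene indices {sorted(overlap)}")
        seen |= set(members)

    loadings = np.zeros((n_genes, max(len(planted_blocks), 1)))
    for b, (members, r) in enumerate(planted_blocks):
        loadings[list(members), b] = np.sqrt(r)
    unique_var = 1.0 - (loadings**2).sum(axis=1)

    if background_sd == 0.0:
        sigma = loadings @ loadings.T + np.diag(unique_var)
    else:
        rng = np.random.default_rng(seed)
        n_samples = max(int(np.ceil(1.0 / background_sd**2)), 3)
        factors = rng.standard_normal((n_samples, loadings.shape[1]))
        noise = rng.standard_normal((n_samples, n_genes)) * np.sqrt(unique_var)
        profiles = factors @ loadings.T + noise
        sigma = np.corrcoef(profiles, rowvar=False)
        sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    return pd.DataFrame(sigma, index=list(gene_names), columns=list(gene_names))
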