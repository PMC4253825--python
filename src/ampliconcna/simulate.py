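"""Synthetic amplicon-sequencing cohorts with planted copy-number truth.

The generator emulates the noise structure of ultra-deep targeted
sequencing at the count level:

* amplicon-specific PCR efficiency — a lognormal multiplier fixed per
  panel (log-sd ``efficiency_sd``, default 0.5): the dominant source of
  between-amplicon coverage spread, shared by every sample run on the
  panel and hence learnable by the PCA baseline;
* GC bias exp(-k (gc - 0.5)^2), unimodal around 50% GC, and length bias
  exp(-k (length - 70)/70), decreasing with fragment size (70-140 bp
  amplicons), both with small per-sample strength jitter so libraries
  differ the way real runs do;
* per-sample technology noise — an independent lognormal multiplier per
  amplicon and sample (log-sd ``sample_noise_sd``, default 0.1);
* Poisson sampling of counts at mean ``depth`` reads per amplicon
  (default 1000);
* chrX dosage halved in male samples;
* tumor CNAs parameterized exactly as the purity model: a gene set gains
  or loses l copies in a fraction c of cells at ploidy P, scaling the
  amplicon rate by ExpectedNRC = (1 - c) + c (1 +/- l/P).

Reads are never synthesized; counts are drawn directly (a tiny SAM
generator for the read-counting tests lives in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import AmpliconPanel, CountMatrix
from .stats import PurityModel, expected_nrc


@dataclass
class CnaSpec:
    """One planted aberration: gene symbols, direction, l copies, fraction c."""

    genes: tuple[str, ...]
    direction: str = "gain"
    l: int = 1
    c: float = 1.0


@dataclass
class SimConfig:
    n_genes: int = 40
    amplicons_per_gene: int = 8
    n_chromosomes: int = 10
    n_chrx_genes: int = 0          # genes placed on chrX (for gender tests)
    gc_range: tuple[float, float] = (0.3, 0.7)
    length_range: tuple[int, int] = (70, 140)
    efficiency_sd: float = 0.5
    gc_bias_strength: float = 4.0
    length_bias_strength: float = 1.0
    sample_noise_sd: float = 0.1
    depth: float = 1000.0          # mean reads per amplicon
    n_controls: int = 15
    control_genders: Optional[Sequence[str]] = None  # default all female
    cna_spec: tuple[CnaSpec, ...] = ()
    ploidy: float = 2.0
    seed: int = 0

    @property
    def n_amplicons(self) -> int:
        return self.n_genes * self.amplicons_per_gene


def simulate_panel(config: SimConfig, rng: Optional[np.random.Generator] = None) -> AmpliconPanel:
    """Panel of contiguous-amplicon genes spread over autosomes (+ chrX)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    n_auto = config.n_genes - config.n_chrx_genes
    per_chrom = int(np.ceil(n_auto / config.n_chromosomes))
    pos = {}
    for g in range(config.n_genes):
        if g < n_auto:
            chrom = f"chr{g // per_chrom + 1}"
        else:
            chrom = "chrX"
        gene = f"GENE{g + 1:03d}"
        start = pos.get(chrom, 10_000)
        for _ in range(config.amplicons_per_gene):
            length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            gc = float(rng.uniform(*config.gc_range))
            rows.append((chrom, start, start + length, gene, gc))
            start += length + int(rng.integers(50, 300))
        pos[chrom] = start + 5_000
    return AmpliconPanel(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "gc"])
    )


def _gc_bias(gc: np.ndarray, strength: float) -> np.ndarray:
    return np.exp(-strength * (gc - 0.5) ** 2)


def _length_bias(length: np.ndarray, strength: float, ref: float = 70.0) -> np.ndarray:
    return np.exp(-strength * (length - ref) / ref)


def simulate_efficiency(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-amplicon PCR efficiency, lognormal with log-sd efficiency_sd."""
    return np.exp(rng.normal(0.0, config.efficiency_sd, config.n_amplicons))


def simulate_counts(
    panel: AmpliconPanel,
    config: SimConfig,
    copy_ratio: np.ndarray,
    efficiency: np.ndarray,
    rng: np.random.Generator,
    male: bool = False,
    bias_jitter: float = 0.2,
) -> np.ndarray:
    """Poisson counts for one sample given per-amplicon copy ratios."""
    cr = np.asarray(copy_ratio, float).copy()
    if male:
        cr = np.where(panel.chrx_mask(), cr * 0.5, cr)
    gc_k = config.gc_bias_strength * (1 + bias_jitter * rng.standard_normal()) \
        if config.gc_bias_strength else 0.0
    len_k = config.length_bias_strength * (1 + bias_jitter * rng.standard_normal()) \
        if config.length_bias_strength else 0.0
    rate = (
        config.depth
        * efficiency
        * _gc_bias(panel.gc, gc_k)
        * _length_bias(panel.length, len_k)
        * cr
        * np.exp(rng.normal(0.0, config.sample_noise_sd, len(panel)))
    )
    return rng.poisson(rate).astype(np.int64)


def truth_ratios(panel: AmpliconPanel, config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-amplicon true copy ratios and the per-gene truth table."""
    ratios = np.ones(len(panel))
    by_gene = {g: "neutral" for g in dict.fromkeys(panel.genes)}
    detail = {g: (0, 0.0, 1.0) for g in by_gene}
    for spec in config.cna_spec:
        r = expected_nrc(PurityModel(spec.c, spec.l, config.ploidy, spec.direction))
        for gene in spec.genes:
            ids = np.flatnonzero(panel.genes == gene)
            ratios[ids] = r
            by_gene[gene] = spec.direction
            detail[gene] = (spec.l, spec.c, r)
    truth = pd.DataFrame(
        [
            (g, by_gene[g], *detail[g])
            for g in by_gene
        ],
        columns=["gene", "status", "l", "c", "expected_nrc"],
    )
    return ratios, truth


def simulate_cohort(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, np.ndarray]:
    """Controls (copy-neutral, per-gender chrX) plus one tumor per cohort.

    Returns (CountMatrix with controls then the tumor, per-gene truth
    table, per-amplicon true copy ratios of the tumor).
    """
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    efficiency = simulate_efficiency(config, rng)
    genders = list(config.control_genders or ["female"] * config.n_controls)
    if len(genders) != config.n_controls:
        raise ValueError("control_genders length must equal n_controls")
    cols, names = [], []
    neutral = np.ones(len(panel))
    for i, g in enumerate(genders):
        cols.append(
            simulate_counts(panel, config, neutral, efficiency, rng, male=(g == "male"))
        )
        names.append(f"C{i + 1:02d}")
    ratios, truth = truth_ratios(panel, config)
    cols.append(simulate_counts(panel, config, ratios, efficiency, rng))
    names.append("T01")
    counts = pd.DataFrame(np.column_stack(cols), columns=names)
    return CountMatrix(panel, counts, {}), truth, ratios
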