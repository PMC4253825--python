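"""Two-phase orchestration: control baseline construction, tumor calling.

Phase 1 (controls): count/normalize each diploid control, call genders
from chrX dosage and double male chrX counts, build the PCA baseline on
the re-normalized cohort, and learn the per-amplicon noise model
sigma_i = f(PC1).  Phase 2 (tumors): normalize, regress on the baseline,
segment with weighted CBS, locate the copy-neutral level, calibrate,
readjust intragenic breakpoints, validate candidates with the fixed
variance test + t-test + purity band, and report per-amplicon outliers.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import baseline as bl
from . import normalize as nm
from . import segment as sg
from . import stats as st
from .amplicon_io import CountMatrix

log = logging.getLogger("ampliconcna")


@dataclass
class RunConfig:
    loess_span: float = 0.3
    n_pcs: Optional[int] = None
    min_mean_nrc: float = 0.01
    gender_threshold: float = 0.9
    cbs_alpha: float = 0.01
    cbs_permutations: int = 1000
    zero_draws: int = 50
    max_components: int = 9
    readjust_alpha: float = 0.01
    p_threshold: float = st.DEFAULT_P_THRESHOLD
    ratio_band: tuple[float, float] = st.DEFAULT_RATIO_BAND
    outlier_q: float = 0.05
    ploidy: int = 2
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ControlPhaseResult:
    baseline: bl.Baseline
    genders: list[nm.GenderCall]
    qc: dict


def run_control_phase(
    counts: CountMatrix,
    config: RunConfig = RunConfig(),
    control_names: Optional[Sequence[str]] = None,
) -> ControlPhaseResult:
    """Build the baseline and noise model from >=2 diploid controls."""
    panel = counts.panel
    names = list(control_names or counts.samples)
    if len(names) < 2:
        raise ValueError("at least two control samples are necessary")
    profiles = [
        nm.normalize_sample(
            counts.column(s), panel, sample=s, span=config.loess_span,
            n_total=counts.total_reads.get(s),
        )
        for s in names
    ]
    genders = nm.infer_gender(
        profiles, panel, threshold=config.gender_threshold, seed=config.seed
    )
    corrected_profiles = []
    for s, g in zip(names, genders):
        col = nm.apply_gender_correction(counts.column(s), g, panel).counts
        corrected_profiles.append(
            nm.normalize_sample(col, panel, sample=s, span=config.loess_span)
        )
    base = bl.build_baseline(
        corrected_profiles, panel, n_pcs=config.n_pcs, min_mean_nrc=config.min_mean_nrc
    )
    ratios = [bl.regress_on_baseline(p, base) for p in corrected_profiles]
    bl.fit_sigma(ratios, base, span=config.loess_span)
    qc = {
        "explained_variance": list(map(float, base.explained_variance)),
        "k": base.k,
        "genders": {g.sample: g.gender for g in genders},
        "n_masked": int((~base.mask).sum()),
    }
    log.info("baseline: k=%d, explained variance=%s", base.k, qc["explained_variance"])
    return ControlPhaseResult(base, genders, qc)


@dataclass
class TumorResult:
    sample: str
    calibrated: sg.CalibratedProfile
    segments: pd.DataFrame
    genes: pd.DataFrame
    amplicons: pd.DataFrame

    @property
    def n_cna_calls(self) -> int:
        return int((self.genes["status"] != "neutral").sum())


def _annotate_segments(
    segments: Sequence[sg.Segment],
    calibrated: sg.CalibratedProfile,
    config: RunConfig,
) -> pd.DataFrame:
    rows = []
    lr = calibrated.log_ratio
    sig = calibrated.sigma_i_sample
    for s in segments:
        ids = s.amplicon_ids
        x = lr[ids] / sig[ids]
        p_fixed = st.fixed_variance_test(x)
        p_t = st.t_test_segment(x)
        ratio = st.weighted_geometric_mean(np.exp(lr[ids]), 1.0 / sig[ids] ** 2)
        rows.append(
            {
                "chrom": s.chrom,
                "first": s.first,
                "last": s.last,
                "n": s.n,
                "log_ratio": s.wmean,
                "ratio": ratio,
                "status": s.status,
                "copies": sg.estimate_copies(ratio, config.ploidy) if ratio > 0 else -1,
                "p_fixed": p_fixed,
                "p_t": p_t,
            }
        )
    df = pd.DataFrame(rows)
    return st.filter_candidates(df, config.p_threshold, config.ratio_band)


def _gene_table(
    segments: Sequence[sg.Segment],
    seg_df: pd.DataFrame,
    calibrated: sg.CalibratedProfile,
    panel,
    config: RunConfig,
) -> pd.DataFrame:
    seg_of = {}
    for si, s in enumerate(segments):
        for a in s.amplicon_ids:
            seg_of[int(a)] = si
    rows = []
    lr = calibrated.log_ratio
    sig = calibrated.sigma_i_sample
    for gene, ids in panel.gene_ranges().items():
        ids = np.array([a for a in ids if int(a) in seg_of])
        if ids.size == 0:
            rows.append({"gene": gene, "status": "NA", "ratio": np.nan,
                         "copies": -1, "n_amplicons": 0, "filter": "no_data"})
            continue
        labels = np.array([seg_of[int(a)] for a in ids])
        major = int(np.bincount(labels).argmax())
        ratio = st.weighted_geometric_mean(np.exp(lr[ids]), 1.0 / sig[ids] ** 2)
        rows.append(
            {
                "gene": gene,
                "status": seg_df.at[major, "status"],
                "ratio": ratio,
                "copies": sg.estimate_copies(ratio, config.ploidy) if ratio > 0 else -1,
                "n_amplicons": int(ids.size),
                "filter": seg_df.at[major, "filter"],
            }
        )
    return pd.DataFrame(rows)


def run_tumor_phase(
    counts: np.ndarray,
    panel,
    base: bl.Baseline,
    config: RunConfig = RunConfig(),
    sample: str = "tumor",
    n_total: Optional[int] = None,
) -> TumorResult:
    """Process one tumor count column against an existing baseline."""
    if base.panel_hash != panel.panel_hash():
        raise ValueError("panel hash mismatch: baseline built on a different panel")
    if base.sigma_i is None:
        raise ValueError("baseline has no sigma_i; run the control phase first")
    profile = nm.normalize_sample(
        counts, panel, sample=sample, span=config.loess_span, n_total=n_total
    )
    ratio = bl.regress_on_baseline(profile, base)
    segments = sg.segment_profile(
        ratio, base.sigma_i, panel,
        alpha=config.cbs_alpha, nperm=config.cbs_permutations, seed=config.seed,
    )
    zero = sg.find_zero_level(
        segments, seed=config.seed, m_draws=config.zero_draws,
        max_components=config.max_components,
    )
    calibrated, segments = sg.calibrate(ratio, segments, zero, base.sigma_i)
    segments = sg.readjust_gene_breakpoints(
        segments, calibrated, panel, alpha=config.readjust_alpha
    )
    seg_df = _annotate_segments(segments, calibrated, config)
    gene_df = _gene_table(segments, seg_df, calibrated, panel, config)
    amp_df = sg.call_outlier_amplicons(calibrated, segments, q_threshold=config.outlier_q)
    log.info(
        "%s: zero level %.4f, sigma_sample %.4f, %d segments, %d CNA genes",
        sample, calibrated.zero_level, calibrated.sigma_sample, len(seg_df),
        int((gene_df["status"] != "neutral").sum()),
    )
    return TumorResult(sample, calibrated, seg_df, gene_df, amp_df)
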