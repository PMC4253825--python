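"""Weighted segmentation and copy-number annotation of log-ratio profiles.

The per-sample log copy-ratio profile is segmented chromosome by
chromosome with a weighted circular binary segmentation (CBS): the test
statistic is the weighted mean difference between a circular arc and its
complement, points weighted by w_i = 1/sigma_i^2 so that amplicons known
to be noisy cannot create breakpoints, and a candidate split is accepted
when it survives a permutation test (default alpha = 0.01, 1000
permutations with early stopping, minimum segment width 2).

The copy-neutral ("zero") level is then found by clustering segment means:
each segment contributes draws from Normal(wmean, sem) — a Parzen-style
resampling so short noisy segments spread out while long segments
concentrate — a 1-D equal-variance Gaussian mixture is selected by BIC
(1..9 components), and the component with the highest peak density is the
neutral level.  Ratios are centered on it, the sample-wide noise scale
sigma_sample is estimated from neutral amplicons, and per-amplicon scales
sigma_i_sample = sigma_sample * sigma_i calibrate all downstream tests.

Breakpoints that fall inside a gene are reconsidered with a gene-aware
t-test: if one adjoining segment's mean explains the whole gene, the break
is moved to the gene boundary.  One-point outliers are reported per
amplicon (Gaussian tail + Benjamini-Hochberg) but never promoted to CNA
calls — single-amplicon events are below the reliable detection limit of
amplicon technology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .baseline import RatioProfile


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    chrom: str
    amplicon_ids: np.ndarray  # panel ids (unmasked), ascending
    wmean: float
    sem: float
    status: str = "neutral"
    cluster: int = -1

    @property
    def n(self) -> int:
        return int(self.amplicon_ids.size)

    @property
    def first(self) -> int:
        return int(self.amplicon_ids[0])

    @property
    def last(self) -> int:
        return int(self.amplicon_ids[-1])


def _weighted_summary(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted mean and its standard error (empirical weighted variance)."""
    W = w.sum()
    wm = float((w * x).sum() / W)
    n = x.size
    if n < 2:
        return wm, float(1.0 / np.sqrt(W))
    v = float((w * (x - wm) ** 2).sum() / W) * n / (n - 1)
    return wm, float(np.sqrt(max(v, 1e-12) / n))


# -- weighted circular max-shift statistic ----------------------------------

def _valid_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Arc boundaries (i, j), arc = [i, j), such that every resulting piece
    has at least 2 points (or is empty)."""
    i, j = np.triu_indices(n + 1, k=2)
    ell = j - i
    keep = (ell <= n - 2) & ((i == 0) | (i >= 2)) & ((j == n) | (j <= n - 2))
    return i[keep], j[keep]

def _max_shift(x, w, ii, jj) -> tuple[float, int, int]:
    """Max |Z| over circular arcs; Z compares arc vs complement weighted means."""
    C = np.concatenate(([0.0], np.cumsum(w)))
    D = np.concatenate(([0.0], np.cumsum(w * x)))
    W1 = C[jj] - C[ii]
    S1 = D[jj] - D[ii]
    W2 = C[-1] - W1
    S2 = D[-1] - S1
    Z = np.abs(S1 / W1 - S2 / W2) / np.sqrt(1.0 / W1 + 1.0 / W2)
    k = int(np.argmax(Z))
    return float(Z[k]), int(ii[k]), int(jj[k])


def _split_once(
    x: np.ndarray,
    w: np.ndarray,
    rng: np.random.Generator,
    alpha: float,
    nperm: int,
) -> Optional[tuple[int, int]]:
    """Permutation-tested circular split; None if not significant."""
    n = x.size
    if n < 4:
        return None
    ii, jj = _valid_pairs(n)
    z_obs, bi, bj = _max_shift(x, w, ii, jj)
    if z_obs <= 0:
        return None
    limit = alpha * nperm
    exceed = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        z_p, _, _ = _max_shift(x[perm], w[perm], ii, jj)
        if z_p >= z_obs:
            exceed += 1
            if exceed > limit:  # p-value can no longer reach alpha
                return None
    if exceed / nperm < alpha:
        return bi, bj
    return None


def _segment_indices(
    x: np.ndarray,
    w: np.ndarray,
    rng: np.random.Generator,
    alpha: float,
    nperm: int,
) -> list[tuple[int, int]]:
    """Recursive CBS over positions [0, n); returns ordered (start, stop)."""
    out: list[tuple[int, int]] = []
    stack = [(0, x.size)]
    while stack:
        a, b = stack.pop()
        split = _split_once(x[a:b], w[a:b], rng, alpha, nperm)
        if split is None:
            out.append((a, b))
            continue
        i, j = split
        pieces = [(a, a + i), (a + i, a + j), (a + j, b)]
        for p in pieces:
            if p[1] > p[0]:
                stack.append(p)
    return sorted(out)


def segment_profile(
    profile: RatioProfile,
    sigma_i: np.ndarray,
    panel,
    alpha: float = 0.01,
    nperm: int = 1000,
    seed: int = 0,
) -> list[Segment]:
    """Weighted CBS of one sample's log-ratio profile, per chromosome."""
    rng = np.random.default_rng(seed)
    lr = profile.log_ratio
    usable = profile.mask & np.isfinite(lr) & np.isfinite(sigma_i)
    weights = np.zeros_like(lr)
    weights[usable] = 1.0 / sigma_i[usable] ** 2
    segments: list[Segment] = []
    for chrom, ids in panel.chrom_groups():
        ids = ids[usable[ids]]
        if ids.size == 0:
            continue
        x, w = lr[ids], weights[ids]
        for a, b in _segment_indices(x, w, rng, alpha, nperm):
            wm, sem = _weighted_summary(x[a:b], w[a:b])
            segments.append(Segment(chrom, ids[a:b], wm, sem))
    return segments


# ---------------------------------------------------------------------------
# zero level by mixture clustering of segment means
# ---------------------------------------------------------------------------

@dataclass
class ZeroLevel:
    zero_level: float
    neutral_component: int
    labels: np.ndarray           # mixture component per segment
    component_means: np.ndarray
    n_components: int


def find_zero_level(
    segments: Sequence[Segment],
    seed: int = 0,
    m_draws: int = 50,
    max_components: int = 9,
) -> ZeroLevel:
    """Cluster segment means; the highest-density component is neutral.

    Each segment is resampled m_draws times from Normal(wmean, sem) so the
    clustering sees segment reliability; the mixture (equal variance,
    component count by BIC) is evaluated at each component mean and the
    peak (ties toward the mean closest to 0) defines copy-neutrality.
    """
    if len(segments) == 0:
        raise ValueError("no segments")
    wmeans = np.array([s.wmean for s in segments])
    if len(segments) == 1:
        return ZeroLevel(float(wmeans[0]), 0, np.zeros(1, int), wmeans.copy(), 1)
    rng = np.random.default_rng(seed)
    draws = np.concatenate(
        [rng.normal(s.wmean, max(s.sem, 1e-6), m_draws) for s in segments]
    ).reshape(-1, 1)
    best_gm, best_bic = None, np.inf
    kmax = min(max_components, len(segments))
    for k in range(1, kmax + 1):
        gm = GaussianMixture(
            k, covariance_type="tied", n_init=2, random_state=seed
        ).fit(draws)
        bic = gm.bic(draws)
        if bic < best_bic - 1e-9:
            best_gm, best_bic = gm, bic
    means = best_gm.means_.ravel()
    sd = float(np.sqrt(best_gm.covariances_.ravel()[0]))
    peak = best_gm.weights_ / (sd * np.sqrt(2 * np.pi))
    order = sorted(
        range(len(means)), key=lambda c: (-peak[c], abs(means[c]))
    )
    neutral = order[0]
    labels = best_gm.predict(wmeans.reshape(-1, 1))
    if not (labels == neutral).any():
        # no actual segment mean in the peak component: fall back to the
        # segment closest to the neutral mean
        labels[np.argmin(np.abs(wmeans - means[neutral]))] = neutral
    return ZeroLevel(float(means[neutral]), int(neutral), labels, means, len(means))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibratedProfile:
    sample: str
    log_ratio: np.ndarray       # centered on the zero level
    mask: np.ndarray
    zero_level: float
    sigma_sample: float
    sigma_i_sample: np.ndarray  # sigma_sample * sigma_i


def calibrate(
    profile: RatioProfile,
    segments: Sequence[Segment],
    zero: ZeroLevel,
    sigma_i: np.ndarray,
) -> tuple[CalibratedProfile, list[Segment]]:
    """Center ratios on the zero level and set the per-sample noise scale.

    sigma_sample is the standard deviation of (centered log ratio /
    sigma_i) over amplicons of copy-neutral segments; statuses of the other
    segments follow the sign of their centered weighted mean.
    """
    neutral_ids = np.concatenate(
        [s.amplicon_ids for s, lab in zip(segments, zero.labels)
         if lab == zero.neutral_component]
        or [np.array([], dtype=int)]
    )
    if neutral_ids.size == 0:
        raise ValueError("zero level undeterminable: no neutral amplicons")
    centered = profile.log_ratio - zero.zero_level
    z = centered[neutral_ids] / sigma_i[neutral_ids]
    z = z[np.isfinite(z)]
    sigma_sample = float(np.std(z, ddof=1)) if z.size > 1 else float(np.abs(z).mean() or 1.0)
    sigma_sample = max(sigma_sample, 1e-6)
    out_segments = []
    for s, lab in zip(segments, zero.labels):
        wm = s.wmean - zero.zero_level
        if lab == zero.neutral_component:
            status = "neutral"
        else:
            status = "gain" if wm > 0 else "loss"
        out_segments.append(replace(s, wmean=wm, status=status, cluster=int(lab)))
    cal = CalibratedProfile(
        sample=profile.sample,
        log_ratio=centered,
        mask=profile.mask,
        zero_level=zero.zero_level,
        sigma_sample=sigma_sample,
        sigma_i_sample=sigma_sample * sigma_i,
    )
    return cal, out_segments


def estimate_copies(ratio: float, ploidy: int = 2) -> int:
    """Round ploidy * linear ratio to the nearest integer copy number.

    Assumes the sample genome is near the stated ploidy and uncontaminated;
    the continuous ratio should always be reported alongside.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return int(round(ploidy * ratio))


# ---------------------------------------------------------------------------
# gene-aware breakpoint readjustment
# ---------------------------------------------------------------------------

def _gene_t_pvalue(values: np.ndarray, mu: float) -> float:
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if values.size < 2 or sd == 0:
        return 1.0 if np.allclose(values, mu) else 0.0
    return float(sps.ttest_1samp(values, mu).pvalue)


def readjust_gene_breakpoints(
    segments: Sequence[Segment],
    calibrated: CalibratedProfile,
    panel,
    alpha: float = 0.01,
) -> list[Segment]:
    """Move intragenic breakpoints to gene boundaries when unjustified.

    For every gene split across segments, each adjoining segment mean is
    tested (one-sample t-test) against all the gene's log ratios; if the
    best-fitting mean is not rejected at ``alpha``, the whole gene is
    reassigned to that segment — a noisy breakpoint a few amplicons off is
    far more common than a true intragenic break.
    """
    lr = calibrated.log_ratio
    seg_of = {}
    for si, s in enumerate(segments):
        for a in s.amplicon_ids:
            seg_of[int(a)] = si
    for gene, ids in panel.gene_ranges().items():
        ids = np.array([a for a in ids if int(a) in seg_of])
        if ids.size == 0:
            continue
        seg_idx = sorted({seg_of[int(a)] for a in ids})
        if len(seg_idx) < 2:
            continue
        pvals = {si: _gene_t_pvalue(lr[ids], segments[si].wmean) for si in seg_idx}
        best = max(pvals, key=pvals.get)
        if pvals[best] > alpha:
            for a in ids:
                seg_of[int(a)] = best
    # rebuild contiguous runs per chromosome from the (possibly moved) labels
    out: list[Segment] = []
    sig = calibrated.sigma_i_sample
    for chrom, ids in panel.chrom_groups():
        ids = [int(a) for a in ids if int(a) in seg_of]
        if not ids:
            continue
        run: list[int] = []
        run_seg = None
        for a in ids:
            if run and seg_of[a] != run_seg:
                out.append(_rebuild_segment(segments[run_seg], np.array(run), lr, sig))
                run = []
            run.append(a)
            run_seg = seg_of[a]
        if run:
            out.append(_rebuild_segment(segments[run_seg], np.array(run), lr, sig))
    return out


def _rebuild_segment(src: Segment, ids: np.ndarray, lr: np.ndarray,
                     sigma_i_sample: np.ndarray) -> Segment:
    w = 1.0 / sigma_i_sample[ids] ** 2
    wm, sem = _weighted_summary(lr[ids], w)
    return Segment(src.chrom, ids, wm, sem, status=src.status, cluster=src.cluster)


# ---------------------------------------------------------------------------
# one-point outliers
# ---------------------------------------------------------------------------

def call_outlier_amplicons(
    calibrated: CalibratedProfile,
    segments: Sequence[Segment],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-amplicon two-sided Gaussian P under Normal(wm_seg, sigma_i_sample),
    Benjamini-Hochberg adjusted across the sample's unmasked amplicons."""
    rows = []
    for si, s in enumerate(segments):
        dev = np.abs(calibrated.log_ratio[s.amplicon_ids] - s.wmean)
        z = dev / calibrated.sigma_i_sample[s.amplicon_ids]
        p = 2 * sps.norm.sf(z)
        for a, lr_a, p_a in zip(s.amplicon_ids, calibrated.log_ratio[s.amplicon_ids], p):
            rows.append((int(a), si, float(lr_a), float(p_a)))
    df = pd.DataFrame(rows, columns=["amplicon_id", "segment", "log_ratio", "p"])
    if len(df):
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
        df["outlier"] = df["q"] < q_threshold
    else:
        df["q"] = []
        df["outlier"] = []
    return df.sort_values("amplicon_id").reset_index(drop=True)
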