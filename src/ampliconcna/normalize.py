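"""Library-specific normalization of per-amplicon read counts.

Three multiplicative corrections are applied in order:

1. library size — raw counts divided by the average count per amplicon
   Avg = N/R, giving NRC_Lib with values near 1 for a copy-neutral,
   bias-free amplicon;
2. GC content — a local quadratic (LOESS, degree 2) fit of log NRC against
   the amplicon GC fraction is removed, since PCR efficiency is a smooth,
   typically unimodal function of GC;
3. amplicon length — the same LOESS detrending against amplicon length,
   shorter fragments amplifying more efficiently.

Corrections are fitted on the log scale and applied multiplicatively:
multiplicative biases are additive in log space, and all downstream
modeling operates on log ratios.  Gender handling doubles chrX counts of
male controls so mixed-gender control cohorts are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

_MIN_LOESS_SUPPORT = 50


# ---------------------------------------------------------------------------
# local polynomial (LOESS) smoother, degree 2, tricube weights
# ---------------------------------------------------------------------------

def loess_predictor(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    max_eval: int = 200,
    trim: float = 0.0,
):
    """Fit a LOESS curve y ~ f(x) and return a vectorized predictor.

    The local polynomial of the given degree is fitted with tricube weights
    over the nearest ``span`` fraction of points, evaluated on a grid of at
    most ``max_eval`` support points and linearly interpolated in between.
    Query points outside the fitted support are clamped to the boundary fit
    value (no extrapolation of the polynomial); ``trim`` shrinks the fitted
    support to the inner (trim, 1 - trim) quantile range, useful when the
    response is noisy and boundary fits would be unstable.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = xs.size
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    if max_eval >= n and trim == 0:
        grid = xs.copy()
    else:
        grid = np.quantile(xs, np.linspace(trim, 1 - trim, min(max_eval, n)))
    fitted = np.empty_like(grid)
    for g, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        # radius = distance to the k-th nearest neighbour
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1.0) * 1e-12
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sel = w > 0
        dx = xs[sel] - x0
        V = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w[sel])
        beta, *_ = np.linalg.lstsq(V * sw[:, None], ys[sel] * sw, rcond=None)
        fitted[g] = beta[0]

    lo, hi = grid[0], grid[-1]

    def predict(xq: np.ndarray) -> np.ndarray:
        xq = np.clip(np.asarray(xq, float), lo, hi)
        return np.interp(xq, grid, fitted)

    return predict


def loess_detrend(
    values: np.ndarray,
    covariate: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Remove a smooth covariate-dependent trend from positive values.

    The trend f is fitted by LOESS to log(values) on the unmasked support;
    corrected values are exp(log v - f + mean f), which preserves the
    geometric mean of the support.  Values off the support (masked or
    non-positive) are returned unchanged.
    """
    values = np.asarray(values, float)
    covariate = np.asarray(covariate, float)
    support = np.isfinite(values) & (values > 0) & np.isfinite(covariate)
    if mask is not None:
        support &= mask
    if support.sum() < _MIN_LOESS_SUPPORT:
        warnings.warn(
            f"only {int(support.sum())} usable amplicons; covariate detrending skipped"
        )
        return values.copy()
    if np.ptp(covariate[support]) < 1e-12:
        warnings.warn("constant covariate; detrending skipped")
        return values.copy()
    logv = np.log(values[support])
    predict = loess_predictor(covariate[support], logv, span=span, degree=degree)
    f = predict(covariate[support])
    out = values.copy()
    out[support] = np.exp(logv - f + f.mean())
    return out


# ---------------------------------------------------------------------------
# normalization pipeline per sample
# ---------------------------------------------------------------------------

def normalize_library_size(counts: np.ndarray, n_total: Optional[int] = None) -> np.ndarray:
    """NRC_Lib = RRC / Avg with Avg = N/R.

    N defaults to the column sum (all reads assigned to amplicons); when the
    sample had unassignable reads the caller passes the true library size
    and the mean NRC_Lib falls below 1 accordingly.
    """
    counts = np.asarray(counts, float)
    n = float(counts.sum() if n_total is None else n_total)
    if n <= 0:
        raise ValueError("empty library (N = 0)")
    avg = n / counts.size
    return counts / avg


@dataclass
class NormalizedProfile:
    """Per-amplicon normalized read counts of one sample, stage by stage."""

    sample: str
    rrc: np.ndarray
    nrc_lib: np.ndarray
    nrc_gc: np.ndarray
    nrc_len: np.ndarray
    mask: np.ndarray  # usable amplicons (non-zero raw count)

    def to_frame(self, panel):
        df = panel.df.copy()
        df["rrc"] = self.rrc
        df["nrc_lib"] = self.nrc_lib
        df["nrc_gc"] = self.nrc_gc
        df["nrc_len"] = self.nrc_len
        df["mask"] = self.mask
        return df


def normalize_sample(
    counts: np.ndarray,
    panel,
    sample: str = "",
    span: float = 0.3,
    n_total: Optional[int] = None,
) -> NormalizedProfile:
    """Apply library-size, GC and length normalization to one count column.

    Amplicons with zero raw count are masked for the sample: a zero at
    amplicon-sequencing depth is an assay failure, not a deep deletion
    signal, and would otherwise dominate the log-scale fits.
    """
    counts = np.asarray(counts)
    mask = counts > 0
    nrc_lib = normalize_library_size(counts, n_total=n_total)
    nrc_gc = loess_detrend(nrc_lib, panel.gc, span=span, mask=mask)
    nrc_len = loess_detrend(nrc_gc, panel.length, span=span, mask=mask)
    return NormalizedProfile(sample, counts.astype(np.int64), nrc_lib, nrc_gc, nrc_len, mask)


# ---------------------------------------------------------------------------
# gender of control samples
# ---------------------------------------------------------------------------

@dataclass
class GenderCall:
    sample: str
    m_value: float
    gender: str  # "male" | "female"
    n_components_selected: int


def infer_gender(
    profiles: Sequence[NormalizedProfile],
    panel,
    threshold: float = 0.9,
    seed: int = 0,
) -> list[GenderCall]:
    """Call control genders from chrX dosage.

    M_i = mean(NRC_Len on chrX) / mean(NRC_Lib) is ~1 for females and ~0.5
    for males.  A 1- vs 2-component Gaussian mixture on {M_i} is selected by
    BIC: two components split the cohort (lower-mean cluster = male); a
    single component is male iff the common M is below ``threshold``.
    """
    chrx = panel.chrx_mask()
    if not chrx.any():
        warnings.warn("panel has no chrX amplicons; all controls labeled female")
        return [
            GenderCall(p.sample, float("nan"), "female", 1) for p in profiles
        ]
    m_values = []
    for p in profiles:
        sup = p.mask & np.isfinite(p.nrc_len)
        num = float(np.mean(p.nrc_len[sup & chrx])) if (sup & chrx).any() else 0.0
        den = float(np.mean(p.nrc_lib[sup]))
        m_values.append(num / den)
    m = np.asarray(m_values)

    n_comp = 1
    if len(m) >= 2 and np.ptp(m) > 0:
        X = m.reshape(-1, 1)
        # reg_covar keeps tiny cohorts from splitting into degenerate
        # zero-variance clusters that BIC would otherwise reward
        fits = {
            k: GaussianMixture(k, reg_covar=1e-3, n_init=3, random_state=seed).fit(X)
            for k in (1, 2)
        }
        n_comp = min(fits, key=lambda k: fits[k].bic(X))
        if n_comp == 2:
            gm = fits[2]
            male_comp = int(np.argmin(gm.means_.ravel()))
            labels = gm.predict(X)
            return [
                GenderCall(p.sample, mi, "male" if lab == male_comp else "female", 2)
                for p, mi, lab in zip(profiles, m, labels)
            ]
    gender = "male" if m.mean() < threshold else "female"
    return [GenderCall(p.sample, mi, gender, 1) for p, mi in zip(profiles, m)]


@dataclass
class CorrectedCounts:
    """Gender-corrected count column; the flag forbids double correction."""

    counts: np.ndarray
    gender_corrected: bool = True


def apply_gender_correction(counts, gender: GenderCall, panel) -> CorrectedCounts:
    """Double chrX counts of male samples; autosomes are never touched."""
    if isinstance(counts, CorrectedCounts):
        raise ValueError("counts already gender-corrected; refusing to reapply")
    counts = np.asarray(counts).copy()
    if gender.gender == "male":
        chrx = panel.chrx_mask()
        counts[chrx] = counts[chrx] * 2
    return CorrectedCounts(counts)
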