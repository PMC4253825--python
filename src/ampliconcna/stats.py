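"""Statistical validation of candidate copy-number aberrations.

Two tests are applied to every non-neutral segment, both on the
standardized values X_i = log(NRC_final_i) / sigma_i_sample, which are
N(0, 1) for copy-neutral amplicons after calibration:

* fixed variance test — |mean(X)| with the variance taken as known;
  mean(X) ~ N(0, 1/n) under the null, so P = 2(1 - Phi(|mean| * sqrt(n)));
  equivalently |mean(X)| follows a half-normal distribution.
* one-sample t-test — the same hypothesis with the variance estimated
  from the segment itself; usually more conservative.

A candidate survives only if both P-values fall below the threshold
(default 0.01) *and* its weighted geometric mean of linear ratios lies
outside the purity band (default 0.875..1.125).  The band encodes a
detection limit on the fraction c of cells carrying the event: the
expected ratio of a gain/loss of l copies in a tumor of ploidy P is

    ExpectedNRC = (1 - c) + c * (1 +/- l / P)

so events carried by fewer than 25%, 33% and 50% of cells in diploid,
triploid and tetraploid tumors respectively cannot exceed the band and
are suppressed rather than reported as unreliable calls.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_RATIO_BAND = (0.875, 1.125)


def fixed_variance_test(x: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Two-sided P for |mean(x)| with unit per-value variance assumed known.

    Under H0 the values are N(0, 1), hence mean ~ N(0, 1/n) and the
    statistic |mean| is half-normal; P = erfc(|mean| * sqrt(n/2)).
    """
    x = np.asarray(x, float)
    if x.shape[axis] == 0:
        raise ValueError("empty segment")
    n = x.shape[axis]
    s = np.abs(x.mean(axis=axis))
    p = special.erfc(s * np.sqrt(n / 2.0))
    return float(p) if np.isscalar(p) or p.ndim == 0 else p


def t_test_segment(x: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Two-sided one-sample t-test of mean 0; NaN when undefined (n < 2 or
    zero spread), which downstream filters treat as a failure."""
    x = np.asarray(x, float)
    n = x.shape[axis]
    if n < 2:
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.asarray(sps.ttest_1samp(x, 0.0, axis=axis).pvalue, float)
    p = np.where(x.std(axis=axis) == 0, np.nan, p)
    return float(p) if np.ndim(p) == 0 else p


@dataclass(frozen=True)
class PurityModel:
    """CNA dosage model: fraction c of cells with +/- l copies at ploidy P."""

    c: float
    l: int = 1
    ploidy: float = 2.0
    direction: str = "gain"

    def __post_init__(self):
        if not 0 <= self.c <= 1:
            raise ValueError("cell fraction c must be in [0, 1]")
        if self.l < 1 or self.ploidy < 1:
            raise ValueError("need l >= 1 and ploidy >= 1")
        if self.direction == "loss" and self.l > self.ploidy:
            raise ValueError("cannot lose more copies than the ploidy")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")


def expected_nrc(model: PurityModel) -> float:
    """Expected linear copy ratio (1 - c) + c (1 +/- l/P)."""
    sign = 1.0 if model.direction == "gain" else -1.0
    return (1.0 - model.c) * 1.0 + model.c * (1.0 + sign * model.l / model.ploidy)


def min_detectable_fraction(
    l: int = 1,
    ploidy: float = 2.0,
    direction: str = "gain",
    band: tuple[float, float] = DEFAULT_RATIO_BAND,
) -> float:
    """Smallest cell fraction whose expected ratio escapes the purity band.

    Solves ExpectedNRC(c) = band edge for c on [0, 1] (gain: upper edge,
    loss: lower edge).  Returns a fraction in [0, 1].
    """
    edge = band[1] if direction == "gain" else band[0]

    def f(c):
        return expected_nrc(PurityModel(c, l, ploidy, direction)) - edge

    if f(1.0) < 0 if direction == "gain" else f(1.0) > 0:
        raise ValueError("event undetectable even in 100% of cells")
    return float(optimize.brentq(f, 0.0, 1.0))


def weighted_geometric_mean(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted geometric mean over positive, finite ratios."""
    ratios = np.asarray(ratios, float)
    weights = np.asarray(weights, float)
    ok = np.isfinite(ratios) & (ratios > 0) & np.isfinite(weights)
    if not ok.any():
        return float("nan")
    return float(np.exp(np.average(np.log(ratios[ok]), weights=weights[ok])))


def filter_candidates(
    calls: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    ratio_band: tuple[float, float] = DEFAULT_RATIO_BAND,
) -> pd.DataFrame:
    """Apply the significance and purity-band filters to candidate CNAs.

    ``calls`` must carry columns status, ratio (weighted geometric mean of
    linear ratios), p_fixed, p_t.  Candidates failing any filter keep their
    row but are demoted to neutral with a reason in ``filter``; undefined
    (NaN) P-values fail conservatively.
    """
    out = calls.copy()
    out["filter"] = "PASS"
    for i in out.index:
        if out.at[i, "status"] == "neutral":
            out.at[i, "filter"] = "."
            continue
        reasons = []
        p_f, p_t = out.at[i, "p_fixed"], out.at[i, "p_t"]
        if not (p_f < p_threshold) or not (p_t < p_threshold):
            reasons.append("significance")
        r = out.at[i, "ratio"]
        if not np.isfinite(r) or ratio_band[0] <= r <= ratio_band[1]:
            reasons.append("purity_band")
        if reasons:
            out.at[i, "status"] = "neutral"
            out.at[i, "filter"] = ",".join(reasons)
    return out
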