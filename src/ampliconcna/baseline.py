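"""Technology-specific normalization via a PCA control baseline.

Even after library-size/GC/length correction, per-amplicon coverage retains
a strong technology footprint (amplicon-specific PCR efficiency) shared
across all samples run on the same platform.  A principal component
analysis of log NRC_Len over a cohort of diploid controls — amplicons as
observations, controls as variables, covariance PCA — captures that
footprint: PC1 essentially *is* the mean efficiency profile, and the next
components pick up residual batch structure.  By default the first three
PCs are kept (or n-1 when fewer than four controls are available; at least
two controls are required).

Each sample's log NRC_Len is then regressed (OLS with intercept) on the
kept PC scores; the residuals are the copy-ratio profile used downstream.
Finally a per-amplicon noise scale sigma_i is learned from the pooled
control residuals as a smooth function of PC1 — high-coverage amplicons
are quieter — via a degree-2 LOESS on squared rescaled residuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .normalize import NormalizedProfile, loess_predictor

SIGMA_FLOOR = 1e-3


@dataclass
class Baseline:
    """Control-derived PCA baseline and per-amplicon noise model."""

    pc_scores: np.ndarray          # (R, k), NaN on masked amplicons
    explained_variance: np.ndarray  # fraction per kept PC
    k: int
    control_names: list[str]
    mask: np.ndarray                # panel-wide usable amplicons
    panel_hash: str
    sigma_i: Optional[np.ndarray] = None  # (R,), NaN on masked amplicons

    # -- serialization: TSV of per-amplicon arrays + JSON sidecar ---------
    def write(self, tsv_path, json_path=None) -> None:
        df = pd.DataFrame(
            self.pc_scores, columns=[f"PC{i+1}" for i in range(self.k)]
        )
        df.insert(0, "amplicon_id", np.arange(len(df)))
        df["sigma_i"] = self.sigma_i if self.sigma_i is not None else np.nan
        df["mask"] = self.mask
        df.to_csv(tsv_path, sep="\t", index=False)
        meta = {
            "k": self.k,
            "explained_variance": list(map(float, self.explained_variance)),
            "control_names": self.control_names,
            "panel_hash": self.panel_hash,
        }
        json_path = json_path or str(tsv_path) + ".json"
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, tsv_path, json_path=None) -> "Baseline":
        df = pd.read_csv(tsv_path, sep="\t")
        json_path = json_path or str(tsv_path) + ".json"
        with open(json_path) as fh:
            meta = json.load(fh)
        k = int(meta["k"])
        return cls(
            pc_scores=df[[f"PC{i+1}" for i in range(k)]].to_numpy(float),
            explained_variance=np.asarray(meta["explained_variance"]),
            k=k,
            control_names=list(meta["control_names"]),
            mask=df["mask"].to_numpy(bool),
            panel_hash=str(meta["panel_hash"]),
            sigma_i=df["sigma_i"].to_numpy(float),
        )


@dataclass
class RatioProfile:
    """Residual log ratios of one sample after regression on the baseline."""

    sample: str
    log_ratio: np.ndarray  # (R,), NaN off mask
    fitted: np.ndarray
    mask: np.ndarray


def _profile_matrix(
    profiles: Sequence[NormalizedProfile], min_mean_nrc: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stack control NRC_Len columns; derive the panel-wide usable mask."""
    nrc_len = np.column_stack([p.nrc_len for p in profiles])
    nrc_lib = np.column_stack([p.nrc_lib for p in profiles])
    masks = np.column_stack([p.mask for p in profiles])
    mask = masks.all(axis=1) & (nrc_len > 0).all(axis=1)
    # amplicons that barely amplify in the whole control cohort are assay
    # failures and are excluded panel-wide
    mask &= nrc_lib.mean(axis=1) >= min_mean_nrc
    return nrc_len, mask


def build_baseline(
    profiles: Sequence[NormalizedProfile],
    panel,
    n_pcs: Optional[int] = None,
    min_mean_nrc: float = 0.01,
) -> Baseline:
    """PCA of control log NRC_Len (amplicons x controls, covariance PCA).

    Keeps k = n_pcs or min(3, n-1) components; PC1's sign is fixed so its
    scores correlate positively with the cross-control mean profile, and
    the other components are oriented by their largest loading, so the
    baseline is reproducible under control relabeling.
    """
    n = len(profiles)
    if n < 2:
        raise ValueError("at least two control samples are necessary")
    nrc_len, mask = _profile_matrix(profiles, min_mean_nrc)
    X = np.log(nrc_len[mask])
    k = min(3, n - 1) if n_pcs is None else min(n_pcs, n - 1, n)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    mean_profile = X.mean(axis=1)
    # orient PC1 along the mean efficiency profile
    if np.corrcoef(scores[:, 0], mean_profile)[0, 1] < 0:
        scores[:, 0] *= -1
    for j in range(1, k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    full = np.full((len(panel), k), np.nan)
    full[mask] = scores
    return Baseline(
        pc_scores=full,
        explained_variance=pca.explained_variance_ratio_.copy(),
        k=k,
        control_names=[p.sample for p in profiles],
        mask=mask,
        panel_hash=panel.panel_hash(),
    )


def regress_on_baseline(profile: NormalizedProfile, baseline: Baseline) -> RatioProfile:
    """OLS of the sample's log NRC_Len on the baseline PC scores.

    The residuals are the log copy-ratio profile: any global multiplicative
    shift of the sample is absorbed by the intercept, and technology bias
    by the PC terms.
    """
    mask = baseline.mask & profile.mask & (profile.nrc_len > 0)
    y = np.log(profile.nrc_len[mask])
    X = np.column_stack([np.ones(mask.sum()), baseline.pc_scores[mask]])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient baseline design; degenerate input")
    fit = X @ beta
    log_ratio = np.full(len(mask), np.nan)
    fitted = np.full(len(mask), np.nan)
    log_ratio[mask] = y - fit
    fitted[mask] = fit
    return RatioProfile(profile.sample, log_ratio, fitted, mask)


def fit_sigma(
    ratio_profiles: Sequence[RatioProfile],
    baseline: Baseline,
    span: float = 0.5,
    floor: float = SIGMA_FLOOR,
) -> np.ndarray:
    """Per-amplicon noise scale sigma_i = f(PC1) from control residuals.

    Each control's residuals are first rescaled to overall variance 1 (some
    libraries are globally noisier); the pooled squared residuals are then
    smoothed against PC1 with a degree-2 LOESS and sigma_i is the square
    root of the (floored) fit.  sigma_i is relative: the absolute per-sample
    scale is re-estimated on neutral regions of each tumor later.
    """
    if len(ratio_profiles) < 2:
        raise ValueError("need residuals from at least two controls")
    mask = baseline.mask
    pc1 = baseline.pc_scores[mask, 0]
    xs, ys = [], []
    for rp in ratio_profiles:
        r = rp.log_ratio[mask]
        ok = np.isfinite(r)
        s = np.std(r[ok], ddof=1)
        if s <= 0:
            continue
        xs.append(pc1[ok])
        ys.append((r[ok] / s) ** 2)
    # squared residuals are heavy-tailed (chi^2-like): a wide span and a
    # trimmed support keep the boundary of the PC1 range from whipsawing
    predict = loess_predictor(
        np.concatenate(xs), np.concatenate(ys), span=span, trim=0.02
    )
    sigma = np.sqrt(np.maximum(predict(pc1), floor))
    full = np.full(len(mask), np.nan)
    full[mask] = sigma
    baseline.sigma_i = full
    return full
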