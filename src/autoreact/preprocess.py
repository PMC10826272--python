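"""Bead-array MFI preprocessing.

The raw readout is a wells x analytes matrix of median fluorescent
intensities in two technical replicates.  Preprocessing follows a fixed
order:

1. ``detect_empty_outliers`` — analytes whose empty-well (no-serum) mean
   is high relative to the other analytes' empty-well means; these beads
   bind non-specifically and would inflate any pooled noise estimate.
2. ``noise_thresholds`` — per replicate, pool the remaining empty-well
   readings; the assumed noise floor is their maximum plus one sample
   standard deviation.  Analytes with no sample-well reading strictly
   above the floor carry no signal and are excluded (by default only when
   below the floor in *both* replicates).
3. ``validate_and_merge`` — flag replicate pairs whose difference is a
   robust outlier (provenance only), average the two replicates, and
   subtract each analyte's mean empty-well background.
4. ``weighted_boxcox`` — per-analyte Box-Cox power transform, the exponent
   chosen by (optionally weighted) profile likelihood, to stabilise the
   strong mean-variance coupling of fluorescence data.
5. ``robust_spline_normalize`` — map every well's intensity distribution
   onto a robust reference distribution through a monotone quantile-
   anchored spline, removing well-to-well distributional drift while
   preserving within-well ranks.

``preprocess_pipeline`` runs all five in order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import golden

from .simdata import BeadArrayDataset

__all__ = [
    "NoiseModel",
    "CleanMatrix",
    "NormalizedMatrix",
    "detect_empty_outliers",
    "noise_thresholds",
    "validate_and_merge",
    "weighted_boxcox",
    "robust_spline_normalize",
    "preprocess_pipeline",
]


@dataclass
class NoiseModel:
    """Empty-well background summary and the derived exclusions."""

    empty_means: pd.Series  # per-analyte mean empty-well MFI (both replicates)
    outlier_analytes: set
    threshold_rep1: float
    threshold_rep2: float
    excluded_rep1: set
    excluded_rep2: set
    excluded_analytes: set
    rule: str = "both"


@dataclass
class CleanMatrix:
    """Replicate-averaged, background-subtracted MFI (may contain negatives)."""

    values: pd.DataFrame  # wells x analytes
    provenance: pd.DataFrame  # boolean flags: anomalous replicate pair


@dataclass
class NormalizedMatrix:
    """Variance-stabilised, distribution-aligned intensities."""

    values: pd.DataFrame
    lambdas: pd.Series | None = None  # per-analyte Box-Cox exponent
    spline_anchors: dict | None = None  # well -> (input anchors, output anchors)
    constant_analytes: set = field(default_factory=set)


def detect_empty_outliers(dataset: BeadArrayDataset) -> set:
    """Analytes with unusually high empty-well background.

    Per analyte j, let m_j be the mean of its empty-well readings (both
    replicates pooled).  With M the median and S the sample standard
    deviation of the m_j across analytes, flag {j : m_j > M + S}.
    """
    empty = dataset.wells_with_role("empty")
    if len(empty) < 2:
        raise ValueError("need at least 2 empty wells to model background noise")
    if dataset.mfi_rep1.shape[1] < 2:
        raise ValueError("need at least 2 analytes")
    stacked = pd.concat([dataset.mfi_rep1.loc[empty], dataset.mfi_rep2.loc[empty]])
    m = stacked.mean(axis=0)
    M = float(m.median())
    S = float(m.std(ddof=1))
    if S == 0.0:
        return set()
    return set(m.index[m > M + S])


def empty_well_means(dataset: BeadArrayDataset) -> pd.Series:
    """Per-analyte mean empty-well MFI, pooled over both replicates."""
    empty = dataset.wells_with_role("empty")
    stacked = pd.concat([dataset.mfi_rep1.loc[empty], dataset.mfi_rep2.loc[empty]])
    return stacked.mean(axis=0)


def noise_thresholds(
    dataset: BeadArrayDataset, outliers: set, rule: str = "both"
) -> NoiseModel:
    """Per-replicate noise floors and below-noise analyte exclusion.

    The floor of a replicate is max + 1 sample SD of that replicate's
    pooled empty-well readings, computed after removing the high-background
    outlier analytes.  An analyte is below noise in a replicate when none
    of its sample-well readings strictly exceeds the floor; ``rule="both"``
    excludes analytes below noise in both replicates, ``rule="either"`` in
    at least one.
    """
    if rule not in ("both", "either"):
        raise ValueError("rule must be 'both' or 'either'")
    empty = dataset.wells_with_role("empty")
    keep = [a for a in dataset.analytes if a not in outliers]
    if len(empty) == 0 or len(keep) == 0:
        raise ValueError("empty-well pool is empty; noise model undefined")

    samples = dataset.sample_wells
    thresholds, excluded = [], []
    for rep in (dataset.mfi_rep1, dataset.mfi_rep2):
        pool = rep.loc[empty, keep].to_numpy().ravel()
        thr = float(pool.max() + np.std(pool, ddof=1))
        above = (rep.loc[samples] > thr).any(axis=0)
        thresholds.append(thr)
        excluded.append(set(above.index[~above]))

    if rule == "both":
        final = excluded[0] & excluded[1]
    else:
        final = excluded[0] | excluded[1]
    return NoiseModel(
        empty_means=empty_well_means(dataset),
        outlier_analytes=set(outliers),
        threshold_rep1=thresholds[0],
        threshold_rep2=thresholds[1],
        excluded_rep1=excluded[0],
        excluded_rep2=excluded[1],
        excluded_analytes=final,
        rule=rule,
    )


def validate_and_merge(
    dataset: BeadArrayDataset,
    noise: NoiseModel,
    max_discordance_sd: float = 3.0,
    wells: str = "sample",
) -> CleanMatrix:
    """Average the replicates and subtract empty-well background.

    Replicate pairs whose difference deviates from the analyte's median
    difference by more than ``max_discordance_sd`` robust SDs (1.4826 x
    MAD) are flagged in the provenance matrix; flagged pairs are still
    averaged — the flag identifies, it does not remove.  ``wells="all"``
    keeps control wells in the output (useful for diagnostics); the
    default restricts to serum sample wells.
    """
    if not dataset.mfi_rep1.index.equals(dataset.mfi_rep2.index):
        raise ValueError("replicate matrices have mismatched axes")
    keep = [a for a in dataset.analytes if a not in noise.excluded_analytes]
    idx = dataset.sample_wells if wells == "sample" else dataset.mfi_rep1.index
    r1 = dataset.mfi_rep1.loc[idx, keep]
    r2 = dataset.mfi_rep2.loc[idx, keep]

    d = r1 - r2
    med = d.median(axis=0)
    mad = (d - med).abs().median(axis=0)
    scale = 1.4826 * mad
    with np.errstate(invalid="ignore", divide="ignore"):
        flags = (d - med).abs().to_numpy() > (max_discordance_sd * scale).to_numpy()
    flags = pd.DataFrame(flags, index=d.index, columns=d.columns)
    # Zero robust scale: replicates agree (near-)exactly; nothing anomalous.
    flags.loc[:, (scale == 0).to_numpy()] = False

    merged = (r1 + r2) / 2.0
    merged = merged - noise.empty_means[keep]
    return CleanMatrix(values=merged, provenance=flags)


def _boxcox_transform(x: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-3:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def _boxcox_profile_ll(logx: np.ndarray, w: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Weighted Box-Cox profile log-likelihood on a grid of exponents."""
    n = w.sum()
    small = np.abs(lams) < 1e-12
    lam_safe = np.where(small, 1.0, lams)
    Y = (np.exp(np.outer(lams, logx)) - 1.0) / lam_safe[:, None]
    Y[small] = logx[None, :]
    mean = (Y * w).sum(axis=1) / n
    var = (w * (Y - mean[:, None]) ** 2).sum(axis=1) / n
    var = np.maximum(var, 1e-300)
    return -0.5 * n * np.log(var) + (lams - 1.0) * float((w * logx).sum())


_LAM_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)


def weighted_boxcox(
    clean: CleanMatrix | pd.DataFrame, weights: np.ndarray | None = None
) -> NormalizedMatrix:
    """Per-analyte Box-Cox power transform with profile-likelihood exponent.

    Background-subtracted values may be non-positive, so each analyte is
    first shifted by ``max(0, eps - min)`` with eps = 1e-6 of the analyte's
    range.  The exponent is chosen on a lambda grid over [-2, 2] (step
    0.01) with golden-section refinement around the grid optimum;
    |lambda| < 1e-3 uses the log branch.  ``weights`` (per well) default
    to 1 and multiply each well's likelihood contribution.
    """
    values = clean.values if isinstance(clean, CleanMatrix) else clean
    n_wells = values.shape[0]
    w = np.ones(n_wells) if weights is None else np.asarray(weights, float)
    if w.shape != (n_wells,) or (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative per-well values, not all zero")

    out = np.empty_like(values.to_numpy(float))
    lambdas = np.empty(values.shape[1])
    constant: set = set()
    for j, col in enumerate(values.columns):
        x = values[col].to_numpy(float)
        rng_ = float(x.max() - x.min())
        if rng_ == 0.0:
            constant.add(col)
            lambdas[j] = 1.0
            out[:, j] = x - 1.0
            continue
        eps = 1e-6 * rng_
        shift = max(0.0, eps - float(x.min()))
        xs = x + shift
        logx = np.log(xs)
        ll = _boxcox_profile_ll(logx, w, _LAM_GRID)
        k = int(np.argmax(ll))
        lam = _LAM_GRID[k]
        if 0 < k < len(_LAM_GRID) - 1:
            try:
                lam = float(
                    golden(
                        lambda l: -_boxcox_profile_ll(logx, w, np.array([l]))[0],
                        brack=(_LAM_GRID[k - 1], _LAM_GRID[k], _LAM_GRID[k + 1]),
                    )
                )
            except ValueError:
                pass  # degenerate bracket: keep the grid optimum
        lambdas[j] = lam
        out[:, j] = _boxcox_transform(xs, lam)
    if constant:
        warnings.warn(f"{len(constant)} constant analyte(s): lambda fixed to 1")
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=values.index, columns=values.columns),
        lambdas=pd.Series(lambdas, index=values.columns),
        constant_analytes=constant,
    )


_DEFAULT_ANCHORS = 11  # deciles plus both extremes
_ANCHOR_HALF_WINDOW = 0.05  # quantile half-width of the robust anchor bin


def _anchor_values(sorted_vals: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Robust quantile anchors: median of the values whose empirical CDF
    falls within a +/- 0.05 window of each anchor probability.  The
    extreme anchors use one-sided windows rather than the raw min/max —
    sample extremes are far too noisy to anchor a mapping on."""
    n = len(sorted_vals)
    anchors = np.empty(len(probs))
    for i, p in enumerate(probs):
        lo = int(np.ceil(max(p - _ANCHOR_HALF_WINDOW, 0.0) * (n - 1)))
        hi = int(np.floor(min(p + _ANCHOR_HALF_WINDOW, 1.0) * (n - 1)))
        if hi < lo:
            lo = hi = int(round(p * (n - 1)))
        anchors[i] = float(np.median(sorted_vals[lo : hi + 1]))
    return anchors


def robust_spline_normalize(
    matrix: NormalizedMatrix | pd.DataFrame, n_anchors: int = _DEFAULT_ANCHORS
) -> NormalizedMatrix:
    """Monotone quantile-anchored normalization to a robust reference.

    The reference distribution is the per-rank median across wells of the
    sorted values.  Each well is mapped onto it by a monotone piecewise-
    cubic (PCHIP) spline through ``n_anchors`` robust quantile anchors;
    the mapping is constrained non-decreasing, so within-well ranks are
    preserved.  With fewer analytes than anchors the mapping falls back to
    a two-anchor linear stretch.
    """
    if isinstance(matrix, NormalizedMatrix):
        values, lambdas, constant = matrix.values, matrix.lambdas, matrix.constant_analytes
    else:
        values, lambdas, constant = matrix, None, set()
    arr = values.to_numpy(float)
    if np.isnan(arr).any():
        raise ValueError("normalization input must not contain NA")
    n_wells, n_analytes = arr.shape

    sorted_rows = np.sort(arr, axis=1)
    reference = np.median(sorted_rows, axis=0)

    if n_analytes < n_anchors:
        warnings.warn(
            f"only {n_analytes} analytes for {n_anchors} anchors; "
            "falling back to a linear two-anchor mapping"
        )
        probs = np.array([0.0, 1.0])
    else:
        probs = np.linspace(0.0, 1.0, n_anchors)

    ref_anchor = _anchor_values(reference, probs)
    out = np.empty_like(arr)
    anchors: dict = {}
    for i, well in enumerate(values.index):
        x_anchor = _anchor_values(sorted_rows[i], probs)
        y_anchor = np.maximum.accumulate(ref_anchor.copy())
        # Collapse ties in the input anchors (flat stretches of the sample
        # distribution) so the interpolant has strictly increasing knots.
        xs, ys = [], []
        j = 0
        while j < len(x_anchor):
            k = j
            while k + 1 < len(x_anchor) and x_anchor[k + 1] <= x_anchor[j] + 1e-12:
                k += 1
            xs.append(x_anchor[j])
            ys.append(float(np.mean(y_anchor[j : k + 1])))
            j = k + 1
        if len(xs) < 2:
            # Essentially constant well: shift to the reference median.
            out[i] = arr[i] + (float(np.median(reference)) - float(np.median(arr[i])))
            anchors[well] = (np.array(xs), np.array(ys))
            continue
        ys = np.maximum.accumulate(np.asarray(ys))
        spline = PchipInterpolator(np.asarray(xs), ys, extrapolate=True)
        mapped = spline(arr[i])
        # PCHIP through non-decreasing knots is non-decreasing on the knot
        # span; guard the extrapolated tails as well.
        lo_mask = arr[i] < xs[0]
        hi_mask = arr[i] > xs[-1]
        if lo_mask.any() or hi_mask.any():
            d0 = max(float(spline.derivative()(xs[0])), 0.0)
            d1 = max(float(spline.derivative()(xs[-1])), 0.0)
            mapped[lo_mask] = ys[0] + d0 * (arr[i][lo_mask] - xs[0])
            mapped[hi_mask] = ys[-1] + d1 * (arr[i][hi_mask] - xs[-1])
        out[i] = mapped
        anchors[well] = (np.asarray(xs), ys)
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=values.index, columns=values.columns),
        lambdas=lambdas,
        spline_anchors=anchors,
        constant_analytes=constant,
    )


def preprocess_pipeline(
    dataset: BeadArrayDataset,
    max_discordance_sd: float = 3.0,
    exclusion_rule: str = "both",
    n_anchors: int = _DEFAULT_ANCHORS,
    boxcox_weights: np.ndarray | None = None,
) -> tuple[NoiseModel, CleanMatrix, NormalizedMatrix]:
    """Run the full preprocessing chain in its fixed order.

    Returns the noise model, the background-subtracted replicate-averaged
    matrix (the fold-change scale) and the wBC+RSN normalized matrix (the
    testing scale).
    """
    outliers = detect_empty_outliers(dataset)
    noise = noise_thresholds(dataset, outliers, rule=exclusion_rule)
    clean = validate_and_merge(dataset, noise, max_discordance_sd=max_discordance_sd)
    transformed = weighted_boxcox(clean, weights=boxcox_weights)
    normalized = robust_spline_normalize(transformed, n_anchors=n_anchors)
    return noise, clean, normalized
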