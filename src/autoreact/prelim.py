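"""Planar microarray screen: feature filtering, MAD scoring, reactivity calls.

The screen converts raw spot intensities into a binary reactive / not
reactive call per antigen and sample.  Background varies strongly between
print blocks, array batches and sera, so intensities are first expressed
as the number of (unscaled) median absolute deviations above the median of
their own (block, sample) stratum; an antigen is called reactive in a
sample when that robust score exceeds a high cutoff (default 70 MADs), and
shortlisted when it is reactive in at least ``min_samples`` sera.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import PrelimDataset

__all__ = ["MadScores", "ReactivityCalls", "filter_features", "mad_transform", "call_reactive"]


@dataclass
class MadScores:
    """Robust per-stratum scores, in MAD units around the stratum median."""

    scores: pd.DataFrame  # features x samples
    block_map: pd.Series  # feature -> block
    degenerate_features: set = field(default_factory=set)
    antigen_map: pd.Series | None = None  # feature -> antigen id


@dataclass
class ReactivityCalls:
    reactive: pd.DataFrame  # boolean features x samples
    reactive_antigens: set
    cutoff: float
    min_samples: int


def filter_features(
    data: PrelimDataset, min_pixels: int = 30, max_na_fraction: float = 0.25
) -> PrelimDataset:
    """Drop unusable features and resolve duplicate antigen prints.

    Removes features smaller than ``min_pixels`` pixels or flagged during
    image analysis, features whose missing fraction reaches
    ``max_na_fraction`` (boundary inclusive), and, for antigens printed in
    several array batches, every copy except the one from the batch with
    the highest mean green (printing-control) signal.
    """
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    if not 0.0 <= max_na_fraction <= 1.0:
        raise ValueError("max_na_fraction must lie in [0, 1]")

    meta = data.feature_meta
    keep = (meta["pixel_size"] >= min_pixels) & ~meta["flagged"].astype(bool)
    na_frac = data.na_mask.mean(axis=1)
    keep &= na_frac < max_na_fraction  # "at least" the fraction -> excluded

    meta_kept = meta[keep]
    # One batch per antigen: highest mean green signal wins (first on ties).
    best = (
        meta_kept.sort_values("mean_green_signal", ascending=False, kind="stable")
        .groupby("antigen", sort=False)
        .head(1)
        .index
    )
    idx = meta_kept.index[meta_kept.index.isin(best)]

    if len(idx) == 0:
        warnings.warn("all features removed by filtering; returning empty dataset")
    return PrelimDataset(
        signal=data.signal.loc[idx],
        feature_meta=meta.loc[idx],
        na_mask=data.na_mask.loc[idx],
        blocks=sorted(set(meta.loc[idx, "block"])) if len(idx) else [],
    )


def mad_transform(data: PrelimDataset) -> MadScores:
    """Express each reading in MADs around its (block, sample) median.

    The MAD here is the raw median absolute deviation — no 1.4826
    normal-consistency factor — so a score of 70 literally means "70 median
    absolute deviations above the stratum median".  Strata with fewer than
    two usable values or zero MAD cannot support the score; their features
    are flagged and their scores set to NA.
    """
    values = data.signal.where(~data.na_mask)
    scores = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    degenerate: set = set()
    block_map = data.feature_meta["block"]

    for block_id, feats in block_map.groupby(block_map).groups.items():
        sub = values.loc[feats]
        arr = sub.to_numpy(float)
        med = np.nanmedian(arr, axis=0)
        mad = np.nanmedian(np.abs(arr - med), axis=0)
        n_ok = np.sum(~np.isnan(arr), axis=0)
        good = (mad > 0) & (n_ok >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (arr - med) / np.where(good, mad, np.nan)
        scores.loc[feats] = out
        if not good.all():
            degenerate |= set(feats)
    antigen_map = (
        data.feature_meta["antigen"] if "antigen" in data.feature_meta else None
    )
    return MadScores(
        scores=scores,
        block_map=block_map,
        degenerate_features=degenerate,
        antigen_map=antigen_map,
    )


def call_reactive(
    scores: MadScores, cutoff: float = 70.0, min_samples: int = 3
) -> ReactivityCalls:
    """Binary reactivity: score strictly above ``cutoff`` MADs.

    An antigen enters the reactive shortlist when it is reactive in at
    least ``min_samples`` samples.  NA scores never count as reactive.
    """
    if cutoff < 0:
        warnings.warn("negative MAD cutoff: everything above the median is reactive")
    n_samples = scores.scores.shape[1]
    if min_samples > n_samples:
        warnings.warn(
            f"min_samples={min_samples} exceeds the {n_samples} available samples; "
            "no antigen can qualify"
        )
    reactive = scores.scores > cutoff  # NA compares False
    counts = reactive.sum(axis=1)
    qualifying = counts.index[counts >= min_samples]
    if scores.antigen_map is not None:
        reactive_antigens = set(scores.antigen_map.loc[qualifying])
    else:
        reactive_antigens = set(qualifying)
    return ReactivityCalls(
        reactive=reactive,
        reactive_antigens=reactive_antigens,
        cutoff=cutoff,
        min_samples=min_samples,
    )
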