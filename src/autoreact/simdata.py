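"""Seeded synthetic cohorts for autoantibody reactivity profiling.

Two generators are provided, mirroring the two assay stages a serum
autoimmunity screen goes through:

``generate_prelim``
    A planar protein-microarray screen: a features x samples intensity
    matrix organised in print blocks, with per-(block, sample) backgrounds,
    small/flagged spots, missing values, duplicate antigens printed in two
    array batches, and a handful of genuinely reactive antigens.

``generate_bead_array``
    A suspension bead array read out as median fluorescent intensity (MFI)
    per analyte (bead ID) per well, run in two technical replicates.  Wells
    are serum samples (cases and controls), empty wells, pooled-plasma
    technical controls and buffer blanks.  A chosen subset of analytes
    carries a multiplicative case effect; the spiked set is recorded as the
    ground truth so downstream calls can be scored.

The generative model is log-normal per analyte: the natural-log MFI of
analyte *j* in well *i* is

    N(mu_j + b_block(j) + 1{case, j in truth} * delta_j * ln 2, sigma_j^2)

with analyte variances sigma_j^2 drawn from a scaled inverse chi-square
family, so that the empirical-Bayes variance moderation used downstream is
exactly well-specified.  Case effects delta_j are expressed in log2 units,
i.e. they are the simulated log2 fold changes.  Each technical replicate
adds independent Gaussian noise on the log scale before exponentiation.

All randomness flows from a single root seed through independent
``numpy`` seed-sequence substreams (latent signal, replicate 1, replicate
2), so datasets are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "BeadArrayDataset",
    "PrelimDataset",
    "generate_bead_array",
    "generate_prelim",
    "generate_gene_sets",
    "truth_set",
    "write_bead_dataset",
    "read_bead_dataset",
]

# Background (no-serum) wells: low log-normal signal.  Sticky analytes are
# beads with elevated non-specific binding; their empty-well mean is
# inflated so the empty-well outlier rule has real structure to detect.
EMPTY_LOG_MEAN = 3.4  # ln MFI, ~30 units of raw background
EMPTY_LOG_SD = 0.3
STICKY_LOG_BONUS = 2.5


class ConfigurationError(ValueError):
    """Raised for simulation configurations that cannot be generated."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design the package analyses: 30 cases vs
    30 age-matched controls, 256 analytes of which 7 carry case effects
    with log2 fold changes between 0.3 and 1.2, beads coupled in 3 plates
    (blocks), two technical replicates, and a few percent of sticky
    high-background analytes.
    """

    n_cases: int = 30
    n_controls: int = 30
    n_analytes: int = 256
    n_differential: int = 7
    effect_log2fc_range: tuple[float, float] = (0.3, 1.2)
    baseline_log_mfi_mean: float = 6.2  # ln MFI, ~500 raw units
    baseline_log_mfi_sd: float = 1.0
    analyte_sd_shape: float = 8.0  # prior df of the variance family
    analyte_sd_scale: float = 0.30  # prior sd (ln-MFI units)
    replicate_noise_sd: float = 0.10
    n_empty_wells: int = 6
    n_plasma_wells: int = 3
    n_buffer_wells: int = 3
    n_blocks: int = 3
    block_offset_sd: float = 0.10
    sticky_analyte_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_analytes": self.n_analytes,
            "n_differential": self.n_differential,
            "n_empty_wells": self.n_empty_wells,
            "n_plasma_wells": self.n_plasma_wells,
            "n_buffer_wells": self.n_buffer_wells,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if self.n_analytes <= 0:
            raise ConfigurationError("n_analytes must be positive")
        if self.n_cases + self.n_controls <= 0:
            raise ConfigurationError("at least one sample well is required")
        if self.n_differential > self.n_analytes:
            raise ConfigurationError(
                "n_differential cannot exceed n_analytes "
                f"({self.n_differential} > {self.n_analytes})"
            )
        lo, hi = self.effect_log2fc_range
        if lo > hi:
            raise ConfigurationError("effect_log2fc_range must be (lo, hi) with lo <= hi")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if not 0.0 <= self.sticky_analyte_fraction <= 1.0:
            raise ConfigurationError("sticky_analyte_fraction must lie in [0, 1]")
        if self.analyte_sd_shape <= 0 or self.analyte_sd_scale <= 0:
            raise ConfigurationError("variance family parameters must be positive")


@dataclass
class BeadArrayDataset:
    """Two technical-replicate MFI matrices plus well/analyte metadata.

    ``mfi_rep1`` / ``mfi_rep2`` are wells x analytes DataFrames sharing
    identical axes.  ``well_meta`` carries the per-well ``role`` (sample /
    empty / plasma / buffer) and, for sample wells, ``group`` (case /
    control).  ``analyte_meta`` maps each analyte to its print block and
    its associated gene symbols (semicolon-joined; a fragment may represent
    several genes).  ``truth`` is the set of analytes simulated with a case
    effect — empty for real data.
    """

    mfi_rep1: pd.DataFrame
    mfi_rep2: pd.DataFrame
    well_meta: pd.DataFrame
    analyte_meta: pd.DataFrame
    truth: frozenset = frozenset()

    @property
    def analytes(self) -> pd.Index:
        return self.mfi_rep1.columns

    @property
    def sample_wells(self) -> pd.Index:
        return self.well_meta.index[self.well_meta["role"] == "sample"]

    def wells_with_role(self, role: str) -> pd.Index:
        return self.well_meta.index[self.well_meta["role"] == role]

    def groups(self) -> pd.Series:
        """Case/control labels for sample wells, in matrix row order."""
        return self.well_meta.loc[self.sample_wells, "group"]

    def validate(self) -> None:
        if not self.mfi_rep1.index.equals(self.mfi_rep2.index):
            raise ValueError("replicate matrices have mismatched well axes")
        if not self.mfi_rep1.columns.equals(self.mfi_rep2.columns):
            raise ValueError("replicate matrices have mismatched analyte axes")
        if (self.mfi_rep1.to_numpy() < 0).any() or (self.mfi_rep2.to_numpy() < 0).any():
            raise ValueError("MFI values must be non-negative")
        sample = self.well_meta["role"] == "sample"
        if self.well_meta.loc[sample, "group"].isna().any():
            raise ValueError("every sample well needs a case/control label")
        if not self.truth <= set(self.analytes):
            raise ValueError("truth set contains unknown analyte ids")


@dataclass
class PrelimDataset:
    """Planar-array screen: raw intensities with print/imaging metadata.

    ``signal`` is features x samples (raw intensity, MAD transform not yet
    applied).  ``feature_meta`` holds antigen id, print block, array batch,
    spot pixel size, an image-analysis flag and the batch's mean green
    (printing-control) signal.  ``na_mask`` marks missing readings.
    """

    signal: pd.DataFrame
    feature_meta: pd.DataFrame
    na_mask: pd.DataFrame
    blocks: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.signal.shape[0]


def _gene_pool(n_analytes: int) -> list:
    # Roughly half as many genes as fragments: each antigen is represented
    # by ~2 fragments on average and fragments can map to several genes.
    n_genes = max(2, round(0.55 * n_analytes))
    return [f"GENE{i + 1:04d}" for i in range(n_genes)]


def generate_bead_array(config: SimConfig) -> BeadArrayDataset:
    """Simulate a two-replicate suspension bead array cohort."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_rep1, rng_rep2 = (np.random.default_rng(s) for s in ss.spawn(3))

    n_a = config.n_analytes
    analytes = pd.Index([f"AF{j + 1:04d}" for j in range(n_a)], name="analyte")

    wells, roles, groups = [], [], []
    for i in range(config.n_cases):
        wells.append(f"case_{i + 1:02d}"); roles.append("sample"); groups.append("case")
    for i in range(config.n_controls):
        wells.append(f"control_{i + 1:02d}"); roles.append("sample"); groups.append("control")
    for role, count in (
        ("empty", config.n_empty_wells),
        ("plasma", config.n_plasma_wells),
        ("buffer", config.n_buffer_wells),
    ):
        for i in range(count):
            wells.append(f"{role}_{i + 1:02d}"); roles.append(role); groups.append(None)
    well_index = pd.Index(wells, name="well")
    well_meta = pd.DataFrame({"role": roles, "group": groups}, index=well_index)

    # Per-analyte parameters.
    mu = rng_latent.normal(config.baseline_log_mfi_mean, config.baseline_log_mfi_sd, n_a)
    # sigma_j^2 ~ scale^2 * shape / chi2(shape): scaled inverse chi-square.
    sigma2 = (
        config.analyte_sd_scale**2
        * config.analyte_sd_shape
        / rng_latent.chisquare(config.analyte_sd_shape, n_a)
    )
    sigma = np.sqrt(sigma2)
    block = np.arange(n_a) % config.n_blocks
    block_offset = rng_latent.normal(0.0, config.block_offset_sd, config.n_blocks)

    truth_idx = np.sort(
        rng_latent.choice(n_a, size=config.n_differential, replace=False)
    )
    delta = np.zeros(n_a)
    lo, hi = config.effect_log2fc_range
    delta[truth_idx] = rng_latent.uniform(lo, hi, config.n_differential)
    truth = frozenset(analytes[truth_idx])

    sticky = rng_latent.random(n_a) < config.sticky_analyte_fraction
    empty_log_mean = np.where(sticky, EMPTY_LOG_MEAN + STICKY_LOG_BONUS, EMPTY_LOG_MEAN)

    # Gene annotation: each fragment maps to one or two genes from the pool.
    pool = _gene_pool(n_a)
    n_genes_per = np.where(rng_latent.random(n_a) < 0.4, 2, 1)
    gene_col = []
    for j in range(n_a):
        picks = rng_latent.choice(len(pool), size=n_genes_per[j], replace=False)
        gene_col.append(";".join(sorted(pool[k] for k in picks)))
    analyte_meta = pd.DataFrame(
        {"genes": gene_col, "block": block, "sticky": sticky}, index=analytes
    )

    n_wells = len(wells)
    latent = np.empty((n_wells, n_a))
    is_case = np.array([g == "case" for g in groups])
    row = 0
    n_samples = config.n_cases + config.n_controls
    base = mu + block_offset[block]
    # Sample wells: analyte-specific variance, case effect on truth analytes.
    eff = delta * math.log(2.0)
    latent[:n_samples] = (
        base
        + is_case[:n_samples, None] * eff
        + rng_latent.standard_normal((n_samples, n_a)) * sigma
    )
    row = n_samples
    # Empty and buffer wells: low background.
    n_bg = config.n_empty_wells
    latent[row : row + n_bg] = empty_log_mean + rng_latent.standard_normal(
        (n_bg, n_a)
    ) * EMPTY_LOG_SD
    row += n_bg
    # Plasma technical controls replicate one fixed pseudo-sample.
    plasma_profile = base + rng_latent.standard_normal(n_a) * sigma
    latent[row : row + config.n_plasma_wells] = plasma_profile
    row += config.n_plasma_wells
    n_buf = config.n_buffer_wells
    latent[row : row + n_buf] = empty_log_mean + rng_latent.standard_normal(
        (n_buf, n_a)
    ) * EMPTY_LOG_SD

    mfi1 = np.exp(latent + rng_rep1.standard_normal(latent.shape) * config.replicate_noise_sd)
    mfi2 = np.exp(latent + rng_rep2.standard_normal(latent.shape) * config.replicate_noise_sd)

    ds = BeadArrayDataset(
        mfi_rep1=pd.DataFrame(mfi1, index=well_index, columns=analytes),
        mfi_rep2=pd.DataFrame(mfi2, index=well_index, columns=analytes),
        well_meta=well_meta,
        analyte_meta=analyte_meta,
        truth=truth,
    )
    ds.validate()
    return ds


def truth_set(dataset: BeadArrayDataset) -> set:
    """Analytes simulated with a case effect (empty for real data)."""
    return set(dataset.truth)


# Fractions of pathological features in the planar screen; chosen to give
# every filtering rule a non-trivial workload at any array size.
_PRELIM_SMALL_PIXEL_FRAC = 0.03
_PRELIM_FLAGGED_FRAC = 0.02
_PRELIM_HEAVY_NA_FRAC = 0.02
_PRELIM_RANDOM_NA_RATE = 0.01
_PRELIM_DUPLICATE_FRAC = 0.01
_PRELIM_SPIKE_FACTOR = 200.0
_PRELIM_SPIKE_SAMPLES = 3


def generate_prelim(config: SimConfig) -> PrelimDataset:
    """Simulate the planar microarray screen used to shortlist antigens.

    ``config.n_analytes`` is the number of printed features (the screen
    scale is typically thousands); ``config.n_differential`` antigens are
    spiked to extreme reactivity in a few samples.  A small fraction of
    antigens is printed in two array batches with distinct mean green
    (printing-control) signal, mimicking replicate prints.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])

    n_feat = config.n_analytes
    n_samples = config.n_cases + config.n_controls
    features = [f"F{i + 1:05d}" for i in range(n_feat)]
    antigens = [f"AG{i + 1:05d}" for i in range(n_feat)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    block = np.arange(n_feat) % config.n_blocks

    # Log-normal intensities with per-(block, sample) backgrounds.
    bg = rng.normal(0.0, config.block_offset_sd, (config.n_blocks, n_samples))
    log_sig = (
        rng.normal(5.0, EMPTY_LOG_SD, (n_feat, 1))
        + bg[block, :]
        + rng.standard_normal((n_feat, n_samples)) * EMPTY_LOG_SD
    )
    signal = np.exp(log_sig)

    # Reactive antigens: extreme intensity in a few samples each.
    n_spike = min(config.n_differential, n_feat)
    spiked = rng.choice(n_feat, size=n_spike, replace=False)
    for f in spiked:
        cols = rng.choice(n_samples, size=min(_PRELIM_SPIKE_SAMPLES, n_samples), replace=False)
        signal[f, cols] *= _PRELIM_SPIKE_FACTOR

    pixel_size = rng.integers(40, 200, n_feat)
    small = rng.choice(n_feat, size=round(_PRELIM_SMALL_PIXEL_FRAC * n_feat), replace=False)
    pixel_size[small] = rng.integers(5, 30, len(small))
    flagged = np.zeros(n_feat, dtype=bool)
    flagged[rng.choice(n_feat, size=round(_PRELIM_FLAGGED_FRAC * n_feat), replace=False)] = True

    na = rng.random((n_feat, n_samples)) < _PRELIM_RANDOM_NA_RATE
    heavy = rng.choice(n_feat, size=round(_PRELIM_HEAVY_NA_FRAC * n_feat), replace=False)
    for f in heavy:
        cols = rng.choice(n_samples, size=max(1, math.ceil(0.4 * n_samples)), replace=False)
        na[f, cols] = True

    batch = np.zeros(n_feat, dtype=int)
    mean_green = rng.normal(600.0, 60.0, n_feat)

    sig_df = pd.DataFrame(signal, index=pd.Index(features, name="feature"), columns=samples)
    na_df = pd.DataFrame(na, index=sig_df.index, columns=samples)
    meta = pd.DataFrame(
        {
            "antigen": antigens,
            "block": block,
            "batch": batch,
            "pixel_size": pixel_size,
            "flagged": flagged,
            "mean_green_signal": mean_green,
        },
        index=sig_df.index,
    )

    # Duplicate prints: re-print a few antigens in a second batch with its
    # own mean green signal and independently noised intensities.
    n_dup = round(_PRELIM_DUPLICATE_FRAC * n_feat)
    if n_dup:
        dup = rng.choice(n_feat, size=n_dup, replace=False)
        dup_feats = [f"F{n_feat + i + 1:05d}" for i in range(n_dup)]
        dup_sig = signal[dup] * np.exp(rng.standard_normal((n_dup, n_samples)) * 0.1)
        dup_meta = pd.DataFrame(
            {
                "antigen": [antigens[f] for f in dup],
                "block": block[dup],
                "batch": 1,
                "pixel_size": rng.integers(40, 200, n_dup),
                "flagged": False,
                "mean_green_signal": rng.normal(600.0, 60.0, n_dup),
            },
            index=pd.Index(dup_feats, name="feature"),
        )
        sig_df = pd.concat(
            [sig_df, pd.DataFrame(dup_sig, index=dup_meta.index, columns=samples)]
        )
        na_df = pd.concat(
            [na_df, pd.DataFrame(False, index=dup_meta.index, columns=samples)]
        )
        meta = pd.concat([meta, dup_meta])

    return PrelimDataset(
        signal=sig_df,
        feature_meta=meta,
        na_mask=na_df,
        blocks=sorted(set(meta["block"])),
    )


def generate_gene_sets(
    dataset: BeadArrayDataset,
    n_sets: int = 40,
    set_size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
    n_enriched: int = 2,
) -> dict:
    """Synthetic gene-set collection over the dataset's gene universe.

    Returns ``{set name: set of gene symbols}``.  ``n_enriched`` sets are
    seeded with the genes of the truth analytes so an over-representation
    analysis on a well-powered run has genuine signal to find.
    """
    rng = np.random.default_rng(seed)
    universe = sorted({g for gs in dataset.analyte_meta["genes"] for g in gs.split(";")})
    truth_genes = sorted(
        {
            g
            for a in dataset.truth
            for g in dataset.analyte_meta.loc[a, "genes"].split(";")
        }
    )
    lo, hi = set_size_range
    sets = {}
    for i in range(n_enriched):
        size = int(rng.integers(lo, hi + 1))
        members = set(truth_genes)
        extra = [g for g in universe if g not in members]
        if size > len(members) and extra:
            pad = rng.choice(len(extra), size=min(size - len(members), len(extra)), replace=False)
            members |= {extra[k] for k in pad}
        sets[f"ENRICHED_SET_{i + 1}"] = members
    for i in range(n_sets - n_enriched):
        size = int(rng.integers(lo, min(hi, len(universe)) + 1))
        picks = rng.choice(len(universe), size=size, replace=False)
        sets[f"RANDOM_SET_{i + 1:03d}"] = {universe[k] for k in picks}
    return sets


def write_bead_dataset(dataset: BeadArrayDataset, out_dir, sep: str = ",") -> None:
    """Serialize as three tables plus a JSON truth file.

    ``mfi_rep1`` and ``mfi_rep2`` have well ids in column 1 and analyte ids
    in the header; ``metadata`` stacks well rows and analyte rows with a
    ``kind`` discriminator.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "csv" if sep == "," else "tsv"
    dataset.mfi_rep1.to_csv(out / f"mfi_rep1.{ext}", sep=sep)
    dataset.mfi_rep2.to_csv(out / f"mfi_rep2.{ext}", sep=sep)
    wm = dataset.well_meta.reset_index().rename(columns={"well": "id"})
    wm.insert(0, "kind", "well")
    am = dataset.analyte_meta.reset_index().rename(columns={"analyte": "id"})
    am.insert(0, "kind", "analyte")
    pd.concat([wm, am]).to_csv(out / f"metadata.{ext}", sep=sep, index=False)
    (out / "truth.json").write_text(json.dumps(sorted(dataset.truth), indent=0) + "\n")


def read_bead_dataset(in_dir, sep: str = ",") -> BeadArrayDataset:
    """Load a dataset written by :func:`write_bead_dataset` (or real data
    laid out the same way; an absent truth file yields an empty truth set)."""
    src = Path(in_dir)
    ext = "csv" if sep == "," else "tsv"
    rep1 = pd.read_csv(src / f"mfi_rep1.{ext}", sep=sep, index_col=0)
    rep2 = pd.read_csv(src / f"mfi_rep2.{ext}", sep=sep, index_col=0)
    rep1.index.name = rep2.index.name = "well"
    rep1.columns.name = rep2.columns.name = "analyte"
    meta = pd.read_csv(src / f"metadata.{ext}", sep=sep)
    wm = meta[meta["kind"] == "well"].set_index("id")[["role", "group"]]
    wm.index.name = "well"
    am_cols = [c for c in meta.columns if c not in ("kind", "id", "role", "group")]
    am = meta[meta["kind"] == "analyte"].set_index("id")[am_cols]
    am.index.name = "analyte"
    truth_path = src / "truth.json"
    truth = frozenset(json.loads(truth_path.read_text())) if truth_path.exists() else frozenset()
    ds = BeadArrayDataset(rep1, rep2, wm, am, truth)
    ds.validate()
    return ds


def null_config(base: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of ``base`` with all case effects removed (null simulation)."""
    base = base or SimConfig()
    return replace(base, n_differential=0, effect_log2fc_range=(0.0, 0.0), **overrides)
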