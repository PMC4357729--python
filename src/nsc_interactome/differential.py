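"""Intensity-binned robust z-test for differential protein abundance.

Spectral-count ratios are noisier for low-abundance proteins, so the log2
ratio r = log2(differentiating / proliferating) is standardized within
bins of similar intensity I = log2(mean count).  Within each bin the mean
and SD are computed after trimming a fixed fraction (default 2.5%) of
extreme ratios on both sides; every member of the bin — including the
trimmed ones — is then standardized with the same (mu_b, sigma_b), i.e.
the within-bin standardization is extrapolated linearly beyond the trimmed
range.  The z-score is converted to a normal-theory p-value, and a protein
is called differentially abundant when p < alpha (default 0.1) AND
|r| > lfc_threshold (default 0.5), both strict.

Because a trimmed SD systematically underestimates the SD of a normal
sample, it is divided by the truncated-normal consistency constant
sqrt(1 - 2*a*phi(a) / (2*Phi(a) - 1)), a = Phi^{-1}(1 - trim_fraction)
(~0.8711 for 2.5% per side), so that z is calibrated under normality.
The correction can be switched off to mimic a naive trimmed z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialConfig:
    trim_fraction: float = 0.025    # trimmed per side
    bin_target: int = 150           # target proteins per intensity bin
    bin_minimum: int = 50           # trailing bin below this is merged
    alpha_diff: float = 0.1
    lfc_threshold: float = 0.5
    two_sided: bool = True
    consistency_correction: bool = True
    normalize_depth: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be nonnegative")
        if self.bin_target < 1 or self.bin_minimum < 1:
            raise ValueError("bin sizes must be positive")


@dataclass(frozen=True)
class BinStats:
    """Trimmed location/scale of the log2 ratios in one intensity bin."""

    index: int
    intensity_min: float
    intensity_max: float
    n: int
    n_trimmed: int          # members remaining after trimming
    mean: float             # trimmed mean of log2 ratios
    sd: float               # trimmed, consistency-corrected SD
    degenerate: bool = False  # fell back to the pooled SD (or worse)


def trim_consistency_factor(trim_fraction: float) -> float:
    """SD shrinkage of a two-sided trimmed normal sample.

    For trim fraction f per side, a symmetric trim retains the central
    1 - 2f of the distribution; the SD of that truncated normal is
    sqrt(1 - 2*a*phi(a)/(2*Phi(a) - 1)) with a = Phi^{-1}(1 - f).
    Dividing a trimmed SD by this factor makes it consistent for the
    untrimmed sigma. f = 0 returns 1.
    """
    if trim_fraction == 0:
        return 1.0
    a = stats.norm.ppf(1.0 - trim_fraction)
    return float(np.sqrt(1.0 - 2.0 * a * stats.norm.pdf(a) / (2.0 * stats.norm.cdf(a) - 1.0)))


def assign_bins(intensities: np.ndarray, ids: list[str] | np.ndarray,
                cfg: DifferentialConfig = DifferentialConfig()) -> np.ndarray:
    """Cut proteins into consecutive equal-occupancy intensity bins.

    Proteins are sorted by intensity (ties broken by protein id so the
    result is independent of input order) and chunked into bins of
    ``bin_target``; a trailing bin smaller than ``bin_minimum`` is merged
    into its neighbor.  Returns a bin index per input position.
    """
    intensities = np.asarray(intensities, dtype=float)
    n = len(intensities)
    if n == 0:
        return np.zeros(0, dtype=int)
    if not np.all(np.isfinite(intensities)):
        raise ValueError("intensities must be finite")
    order = np.lexsort((np.asarray(ids, dtype=object), intensities))
    sizes = [cfg.bin_target] * (n // cfg.bin_target)
    if n % cfg.bin_target:
        sizes.append(n % cfg.bin_target)
    if len(sizes) > 1 and sizes[-1] < cfg.bin_minimum:
        trailing = sizes.pop()
        sizes[-1] += trailing
    bins = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes):
        bins[order[start:start + size]] = b
        start += size
    return bins


def trimmed_bin_stats(ratios: np.ndarray, cfg: DifferentialConfig,
                      index: int = 0,
                      intensity_range: tuple[float, float] = (float("nan"), float("nan")),
                      ) -> BinStats:
    """Trimmed mean and consistency-corrected SD of one bin's log2 ratios.

    k = floor(trim_fraction * n) smallest and k largest ratios are removed;
    the remainder gives the sample mean and SD (ddof=1).  A zero trimmed SD
    marks the bin degenerate; the caller substitutes the pooled SD.
    """
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios)
    if n < 3:
        raise ValueError("a bin needs at least 3 members")
    k = int(np.floor(cfg.trim_fraction * n))
    kept = np.sort(ratios)[k:n - k]
    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1))
    if cfg.consistency_correction:
        sd /= trim_consistency_factor(cfg.trim_fraction)
    return BinStats(
        index=index,
        intensity_min=intensity_range[0],
        intensity_max=intensity_range[1],
        n=n,
        n_trimmed=len(kept),
        mean=mean,
        sd=sd,
        degenerate=(sd == 0.0),
    )


def standardize_ratios(ids: list[str] | np.ndarray,
                       intensities: np.ndarray,
                       ratios: np.ndarray,
                       cfg: DifferentialConfig = DifferentialConfig(),
                       ) -> tuple[pd.DataFrame, list[BinStats]]:
    """Bin by intensity, standardize log2 ratios, convert z to p.

    The workhorse behind :func:`differential_test`, usable directly on any
    (intensity, log2 ratio) pairs.  Returns a per-protein frame with
    columns protein_id, intensity, log2_ratio, bin, z, pvalue plus the
    per-bin statistics.  Proteins whose bin has zero spread everywhere get
    p = 1 (no evidence against the bin-wide value).
    """
    ids = list(ids)
    intensities = np.asarray(intensities, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if not (len(ids) == len(intensities) == len(ratios)):
        raise ValueError("ids, intensities and ratios must have equal length")
    if len(ids) == 0:
        empty = pd.DataFrame(columns=["protein_id", "intensity", "log2_ratio",
                                      "bin", "z", "pvalue"])
        return empty, []
    bins = assign_bins(intensities, ids, cfg)
    raw: list[BinStats] = []
    for b in range(bins.max() + 1):
        mask = bins == b
        raw.append(trimmed_bin_stats(
            ratios[mask], cfg, index=b,
            intensity_range=(float(intensities[mask].min()),
                             float(intensities[mask].max())),
        ))
    # pooled SD over non-degenerate bins for the zero-spread fallback
    good = [s for s in raw if not s.degenerate]
    if good:
        num = sum((s.n_trimmed - 1) * s.sd ** 2 for s in good)
        den = sum(s.n_trimmed - 1 for s in good)
        pooled = float(np.sqrt(num / den)) if den > 0 else 0.0
    else:
        pooled = 0.0
        logger.warning("all intensity bins have zero trimmed spread; "
                       "p-values set to 1")
    bin_stats: list[BinStats] = []
    for s in raw:
        if s.degenerate and pooled > 0:
            s = BinStats(s.index, s.intensity_min, s.intensity_max,
                         s.n, s.n_trimmed, s.mean, pooled, degenerate=True)
        bin_stats.append(s)

    z = np.empty(len(ids))
    for s in bin_stats:
        mask = bins == s.index
        if s.sd > 0:
            z[mask] = (ratios[mask] - s.mean) / s.sd
        else:
            z[mask] = 0.0
    if cfg.two_sided:
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    else:
        pvals = stats.norm.sf(z)
    table = pd.DataFrame({
        "protein_id": ids,
        "intensity": intensities,
        "log2_ratio": ratios,
        "bin": bins,
        "z": z,
        "pvalue": pvals,
    })
    return table, bin_stats


def differential_test(counts: pd.DataFrame,
                      cfg: DifferentialConfig = DifferentialConfig(),
                      ) -> tuple[pd.DataFrame, list[BinStats]]:
    """Differential-abundance calls between differentiating and proliferating NSCs.

    ``counts`` holds one row per protein with columns protein_id,
    differentiating, proliferating; every protein must have both counts
    positive (guaranteed upstream by the enriched & in-both filter).

    With ``normalize_depth`` the two samples' counts are rescaled so their
    totals equal the mean total before intensities and ratios are formed.
    Returns the per-protein record table (adds normalized counts,
    direction and the differential flag to the standardized columns) and
    the bin statistics.
    """
    required = {"protein_id", "differentiating", "proliferating"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts frame needs columns {sorted(required)}")
    if len(counts) == 0:
        empty = pd.DataFrame(columns=[
            "protein_id", "norm_differentiating", "norm_proliferating",
            "intensity", "log2_ratio", "bin", "z", "pvalue",
            "direction", "differential"])
        return empty, []
    d = counts["differentiating"].to_numpy(dtype=float)
    p = counts["proliferating"].to_numpy(dtype=float)
    if (d <= 0).any() or (p <= 0).any():
        raise ValueError("differential_test requires positive counts in both "
                         "NSC samples (apply the in-both filter first)")
    if cfg.normalize_depth:
        mean_total = (d.sum() + p.sum()) / 2.0
        d = d * (mean_total / d.sum())
        p = p * (mean_total / p.sum())
    intensity = np.log2((d + p) / 2.0)
    ratio = np.log2(d / p)
    table, bin_stats = standardize_ratios(
        list(counts["protein_id"]), intensity, ratio, cfg)
    table.insert(1, "norm_differentiating", d)
    table.insert(2, "norm_proliferating", p)
    table["direction"] = np.select(
        [table["log2_ratio"] > 0, table["log2_ratio"] < 0],
        ["up-in-differentiation", "up-in-maintenance"], default="null")
    table["differential"] = (
        (table["pvalue"] < cfg.alpha_diff)
        & (table["log2_ratio"].abs() > cfg.lfc_threshold)
    )
    return table, bin_stats
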