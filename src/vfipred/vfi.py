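"""The Variant Frequency Index: a per-position tolerance-to-variation score.

The score is built in three stages.

1. **Raw tolerance** ``f``: at each residue position, the summed allele count
   of observed missense variants is divided by ``N * missense_possible``,
   where ``N`` is the total number of sequenced alleles in the population
   panel and ``missense_possible`` is the number of distinct missense
   residues reachable from that codon by a single base change.  Positions
   that tolerate variation in the population accumulate observations and
   score high; constrained positions stay near zero.

2. **Rational squash** ``F = f / (f + alpha)``: maps ``f`` from [0, inf) into
   [0, 1) monotonically.  ``alpha`` sets the curvature — it is exactly the
   raw tolerance at which ``F = 0.5``.

3. **Gaussian smoothing**: ``F`` is treated as a noisy per-position signal
   and denoised by discrete convolution with a normalized Gaussian kernel
   of standard deviation ``sigma`` (in residue positions).  At the sequence
   ends the kernel is truncated to in-range positions and renormalized, so
   a constant profile stays constant.

A rectangular (running-mean) kernel over a 31-residue window is provided as
the classical sliding-window baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import AlleleTable, CodingSequence, missense_possible_per_position


def merge_frequency_sources(table: AlleleTable) -> AlleleTable:
    """Collapse multi-source allele tables to one row per variant.

    When the same variant is reported by several panels, the record from the
    panel with the larger ``total_alleles`` (the larger denominator, hence
    the better-powered frequency estimate) is kept; all other rows are
    redundant and discarded.
    """
    f = table.frame
    if f.empty:
        return AlleleTable(f.copy())
    idx = (
        f.assign(_key=f["variant"].astype(str))
        .sort_values(["_key", "total_alleles"], kind="mergesort")
        .groupby("_key", sort=True)
        .tail(1)
        .index
    )
    merged = f.loc[idx].sort_index().reset_index(drop=True)
    return AlleleTable(merged)


def position_tolerance(
    merged: AlleleTable,
    cds: CodingSequence,
    n_total: int | None = None,
    count_mode: str = "alleles",
) -> np.ndarray:
    """Per-position raw tolerance ``f``.

    ``f[p] = observed(p) / (N * missense_possible(p))`` where ``observed(p)``
    is, by default, the summed allele count over missense variants at
    position ``p`` (``count_mode="alleles"``); ``count_mode="variants"``
    counts distinct observed variants instead.  ``N`` defaults to the
    largest ``total_alleles`` in the merged table — a single gene-wide
    denominator.  Positions with no reachable missense variant get ``f = 0``
    with a warning.
    """
    if count_mode not in ("alleles", "variants"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    possible = missense_possible_per_position(cds)
    length = len(possible)
    if length and possible[-1] == 0 and cds.protein() and len(cds.protein()) < length:
        possible = possible[: len(cds.protein())]  # trailing stop codon
        length = len(possible)
    frame = merged.frame
    if n_total is None:
        if frame.empty:
            raise ValueError("cannot infer N from an empty allele table; pass n_total")
        n_total = int(frame["total_alleles"].max())
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    observed = np.zeros(length)
    for _, row in frame.iterrows():
        pos = row["variant"].position
        if pos > length:
            continue
        observed[pos - 1] += row["allele_count"] if count_mode == "alleles" else 1
    f = np.zeros(length)
    zero_possible = [p + 1 for p in range(length) if possible[p] == 0]
    if zero_possible:
        warnings.warn(
            f"no reachable missense variants at position(s) {zero_possible[:5]}; f set to 0",
            stacklevel=2,
        )
    for p in range(length):
        if possible[p] > 0:
            f[p] = observed[p] / (n_total * possible[p])
    return f


def default_alpha(f: np.ndarray) -> float:
    """Median of the non-zero raw tolerances — centres the squash on typical tolerance."""
    nonzero = f[f > 0]
    if nonzero.size == 0:
        raise ValueError("all positions have f = 0; alpha must be given explicitly")
    return float(np.median(nonzero))


def squash(f, alpha: float):
    """Rational squash ``F = f / (f + alpha)``, a strictly increasing map of
    [0, inf) onto [0, 1) with fixed point ``F(alpha) = 0.5``."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    arr = np.asarray(f, dtype=float)
    if (arr < 0).any():
        raise ValueError("f must be non-negative")
    out = arr / (arr + alpha)
    return float(out) if np.isscalar(f) else out


def gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    """Normalized Gaussian weights exp(-n^2 / 2 sigma^2) for n in [-radius, radius]."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    n = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-(n**2) / (2.0 * sigma**2))
    return w / w.sum()


def default_radius(sigma: float) -> int:
    """Kernel half-width: ceil(4 sigma) captures >99.99% of the Gaussian mass."""
    return max(1, math.ceil(4.0 * sigma))


@dataclass
class ToleranceProfile:
    """Raw and squashed per-position tolerance plus the parameters that made them."""

    f: np.ndarray
    F: np.ndarray
    alpha: float
    n_total: int

    def __post_init__(self) -> None:
        if not np.allclose(self.F, self.f / (self.f + self.alpha)):
            raise ValueError("F does not equal f/(f+alpha)")


@dataclass
class VfiProfile:
    """Gaussian-smoothed tolerance profile."""

    values: np.ndarray
    sigma: float
    radius: int
    edge_policy: str = "renormalize"

    def at(self, position: int) -> float:
        return float(self.values[position - 1])


def _smooth(F: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Centered correlation with truncated-and-renormalized edges.

    Implemented as convolve(F, K) / convolve(1, K): the denominator is the
    in-range kernel mass at each position, so edge weights renormalize to 1
    and a constant profile is preserved exactly.  The kernel is symmetric,
    so convolution and correlation coincide.
    """
    start = (len(kernel) - 1) // 2
    num = np.convolve(F, kernel, mode="full")[start : start + len(F)]
    den = np.convolve(np.ones_like(F), kernel, mode="full")[start : start + len(F)]
    return num / den


def compute_vfi(F, sigma: float = 2.0, radius: int | None = None) -> VfiProfile:
    """Smooth a squashed tolerance profile with a Gaussian kernel.

    ``VFI_n = sum_j K_j F_{n-j}`` with the kernel centered on ``n``; at the
    sequence ends the kernel is truncated to in-range positions and
    renormalized.
    """
    F = np.asarray(F, dtype=float)
    if F.size < 1:
        raise ValueError("profile must have at least one position")
    if radius is None:
        radius = default_radius(sigma)
    kernel = gaussian_kernel(sigma, radius)
    return VfiProfile(values=_smooth(F, kernel), sigma=sigma, radius=radius)


def sliding_window_score(F, window: int = 31) -> np.ndarray:
    """Running mean over an odd window (rectangular kernel), renormalized at the ends."""
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    F = np.asarray(F, dtype=float)
    if F.size < 1:
        raise ValueError("profile must have at least one position")
    kernel = np.full(window, 1.0 / window)
    return _smooth(F, kernel)


def build_position_profile(
    merged: AlleleTable,
    cds: CodingSequence,
    sigma: float = 2.0,
    alpha: float | None = None,
    n_total: int | None = None,
    radius: int | None = None,
    window: int = 31,
    count_mode: str = "alleles",
) -> pd.DataFrame:
    """End-to-end per-position table: position, f, F, VFI and the window baseline."""
    f = position_tolerance(merged, cds, n_total=n_total, count_mode=count_mode)
    if alpha is None:
        alpha = default_alpha(f)
    F = squash(f, alpha)
    vfi = compute_vfi(F, sigma=sigma, radius=radius)
    win = sliding_window_score(F, window=window)
    return pd.DataFrame(
        {
            "position": np.arange(1, f.size + 1),
            "f": f,
            "F": F,
            "vfi": vfi.values,
            f"window{window}": win,
        }
    )
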