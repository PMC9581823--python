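"""Sliding-window dynamic functional connectivity.

The dFC statistic is a per-connection coefficient of variation: for each pair
of regions, the absolute Pearson correlation is computed inside every sliding
window, and the sample standard deviation of those window values is divided
by their mean. Network-level summaries average the statistic over all
connections between a network's members and the rest of the brain (within-
network pairs excluded); the whole-brain summary averages all unique pairs.

Window starts are reported 1-based; internal indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import RegionTable, TimeSeriesMatrix, ValidationError, WindowSpec

#: Connections whose mean windowed correlation falls below this floor are
#: masked (NaN) rather than divided through, to avoid exploding ratios.
DEFAULT_MEAN_FLOOR = 1e-6


@dataclass
class WindowStack:
    """Ordered stack of per-window absolute-correlation matrices.

    ``windows`` has shape (W, N, N); ``window_starts`` holds the 1-based
    first-volume index of each window.
    """

    windows: np.ndarray
    window_starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_regions(self) -> int:
        return self.windows.shape[1]


@dataclass
class DFCMatrix:
    """Symmetric matrix of per-connection coefficients of variation.

    The diagonal and any connection whose mean strength fell below the
    configured floor are NaN and excluded from downstream averages.
    """

    values: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def finite_offdiag_mask(self) -> np.ndarray:
        mask = np.isfinite(self.values)
        np.fill_diagonal(mask, False)
        return mask


def enumerate_windows(n_volumes: int, spec: WindowSpec) -> np.ndarray:
    """1-based start indices of all fully-contained sliding windows.

    Starts are 1, 1+S, 1+2S, ...; only windows lying entirely inside the
    series count (no padding), giving floor((T - L) / S) + 1 windows.
    With the study configuration (T=180, L=28, S=5) this yields 31 windows.
    """
    length, step = spec.length_volumes, spec.step_volumes
    if n_volumes < length:
        raise ValidationError(
            f"series shorter than window: {n_volumes} volumes < length {length}"
        )
    n_windows = (n_volumes - length) // step + 1
    return 1 + step * np.arange(n_windows)


def windowed_abs_correlation(ts: TimeSeriesMatrix, spec: WindowSpec) -> WindowStack:
    """Absolute Pearson correlation matrix for every sliding window."""
    starts = enumerate_windows(ts.n_volumes, spec)
    length = spec.length_volumes
    mats = np.empty((len(starts), ts.n_regions, ts.n_regions))
    for w, start in enumerate(starts):
        seg = ts.data[:, start - 1 : start - 1 + length]
        dead = np.flatnonzero(np.ptp(seg, axis=1) == 0)
        if dead.size:
            raise ValidationError(
                f"zero-variance region (row {dead[0] + 1}, id "
                f"{ts.region_ids[dead[0]]}) in window starting at volume {start}"
            )
        corr = np.corrcoef(seg)
        corr = (corr + corr.T) / 2.0  # enforce exact symmetry
        mats[w] = np.abs(np.clip(corr, -1.0, 1.0))
        np.fill_diagonal(mats[w], 1.0)
    return WindowStack(windows=mats, window_starts=starts)


def cov_dfc(stack: WindowStack, mean_floor: float = DEFAULT_MEAN_FLOOR) -> DFCMatrix:
    """Per-connection coefficient of variation over windows (sample SD / mean)."""
    if stack.n_windows < 2:
        raise ValidationError("coefficient of variation requires at least 2 windows")
    sd = stack.windows.std(axis=0, ddof=1)
    # a connection that is exactly constant over windows has exactly zero
    # dFC; guard against the ~1e-17 residue of the two-pass variance
    sd[np.ptp(stack.windows, axis=0) == 0] = 0.0
    mean = stack.windows.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(mean >= mean_floor, sd / mean, np.nan)
    np.fill_diagonal(values, np.nan)
    return DFCMatrix(values=values)


def network_dfc(dfc: DFCMatrix, regions: RegionTable, network: str) -> float:
    """Mean dFC over all connections between a network and the rest of the brain.

    With m members among N regions, exactly m(N - m) member-to-non-member
    connections enter the (unweighted) average; within-network pairs are
    excluded. "Rest of the brain" includes subcortical regions.
    """
    if network not in ("DMN", "FPN"):
        raise ValidationError(f"network summary defined for DMN/FPN, got {network!r}")
    if regions.n_regions != dfc.n_regions:
        raise ValidationError("region table size does not match dFC matrix")
    members = regions.members(network)
    if members.size == 0:
        raise ValidationError(f"network {network} has no member regions")
    rest = np.setdiff1d(np.arange(dfc.n_regions), members)
    block = dfc.values[np.ix_(members, rest)]
    finite = np.isfinite(block)
    if not finite.any():
        raise ValidationError(f"all {network}-to-rest connections are masked")
    return float(block[finite].mean())


def whole_brain_dfc(dfc: DFCMatrix) -> float:
    """Mean dFC over all N(N-1)/2 unique off-diagonal connections."""
    iu = np.triu_indices(dfc.n_regions, k=1)
    vals = dfc.values[iu]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValidationError("all connections are masked")
    return float(vals[finite].mean())


def dfc_summaries(
    ts: TimeSeriesMatrix,
    regions: RegionTable,
    spec: WindowSpec | None = None,
    mean_floor: float = DEFAULT_MEAN_FLOOR,
) -> dict[str, float]:
    """Convenience: DMN, FPN and whole-brain dFC for one time series."""
    spec = spec if spec is not None else WindowSpec()
    dfc = cov_dfc(windowed_abs_correlation(ts, spec), mean_floor=mean_floor)
    return {
        "DMN_dFC": network_dfc(dfc, regions, "DMN"),
        "FPN_dFC": network_dfc(dfc, regions, "FPN"),
        "WB_dFC": whole_brain_dfc(dfc),
    }
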