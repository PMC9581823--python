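"""Multivariate phase-randomization surrogates and the surrogate dFC test.

The null model asks whether observed connectivity dynamics exceed what
stationarity plus autocorrelation alone produce. Each surrogate is built by
rotating the discrete Fourier phases of every region's series by one common
random phase vector (conjugate-symmetric, DC and Nyquist untouched) and
inverting the transform. Because all regions share the phase rotation, every
cross-spectrum — and hence the full-length correlation matrix — and every
per-region amplitude spectrum are preserved exactly; genuine time-localized
coupling fluctuations are destroyed. Observed whole-brain dFC is then
compared with the surrogate-ensemble mean by a paired t-test across
participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import TimeSeriesMatrix, ValidationError, WindowSpec
from .dfc import DEFAULT_MEAN_FLOOR, cov_dfc, whole_brain_dfc, windowed_abs_correlation

#: Ensemble size used in the study.
DEFAULT_N_COPIES = 20


def _subseed(seed: int, index: int) -> np.random.Generator:
    """Counter-based sub-stream: copy k of master seed s uses spawn key (k,)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def phase_randomize(
    ts: TimeSeriesMatrix,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    phases: np.ndarray | None = None,
) -> TimeSeriesMatrix:
    """One phase-randomized surrogate of a region-by-volume matrix.

    A single phase offset, uniform on [0, 2pi), is drawn per positive
    frequency and applied to every region's spectrum; DC and (for even
    length) the Nyquist bin keep phase 0 so the output stays real.

    ``phases`` is a test hook: an explicit offset vector for the rotatable
    bins (all-zero reproduces the input to numerical precision).
    """
    data = ts.data
    n_volumes = data.shape[1]
    if n_volumes < 4:
        raise ValidationError("phase randomization requires at least 4 volumes")
    if not np.all(np.isfinite(data)):
        raise ValidationError("non-finite values in time series")

    spectra = np.fft.rfft(data, axis=1)
    n_bins = spectra.shape[1]
    # rotatable bins exclude DC (bin 0) and, for even T, the Nyquist bin
    has_nyquist = n_volumes % 2 == 0
    n_free = n_bins - 1 - (1 if has_nyquist else 0)
    if phases is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_free)
    else:
        phases = np.asarray(phases, dtype=float)
        if phases.shape != (n_free,):
            raise ValidationError(f"expected {n_free} phase offsets, got {phases.shape}")
    rotation = np.ones(n_bins, dtype=complex)
    rotation[1 : 1 + n_free] = np.exp(1j * phases)
    surrogate = np.fft.irfft(spectra * rotation, n=n_volumes, axis=1)
    return TimeSeriesMatrix(
        data=surrogate, tr_seconds=ts.tr_seconds, region_ids=list(ts.region_ids)
    )


@dataclass
class SurrogateEnsemble:
    """K phase-randomized copies of one participant-timepoint series.

    Copy k is generated from the sub-stream ``SeedSequence(seed, spawn_key=(k,))``,
    so regeneration from the same (seed, K, input) is bit-identical and copies
    can be produced independently.
    """

    copies: list[TimeSeriesMatrix]
    seed: int

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    @classmethod
    def generate(
        cls, ts: TimeSeriesMatrix, n_copies: int = DEFAULT_N_COPIES, seed: int = 0
    ) -> "SurrogateEnsemble":
        if n_copies < 1:
            raise ValidationError("ensemble size K must be >= 1")
        copies = [phase_randomize(ts, rng=_subseed(seed, k)) for k in range(n_copies)]
        return cls(copies=copies, seed=seed)


def surrogate_whole_brain_dfc(
    ts: TimeSeriesMatrix,
    spec: WindowSpec | None = None,
    n_copies: int = DEFAULT_N_COPIES,
    seed: int = 0,
    mean_floor: float = DEFAULT_MEAN_FLOOR,
) -> float:
    """Mean whole-brain dFC over K phase-randomized surrogates."""
    spec = spec if spec is not None else WindowSpec()
    ensemble = SurrogateEnsemble.generate(ts, n_copies=n_copies, seed=seed)
    values = [
        whole_brain_dfc(cov_dfc(windowed_abs_correlation(copy, spec), mean_floor=mean_floor))
        for copy in ensemble.copies
    ]
    return float(np.mean(values))


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test of observed vs surrogate-mean whole-brain dFC."""

    t_value: float
    df: int
    p_value: float
    mean_difference: float

    def summary(self) -> str:
        return (
            f"Paired surrogate test: t({self.df}) = {self.t_value:.3f}, "
            f"p = {self.p_value:.4f}, mean(observed - surrogate) = "
            f"{self.mean_difference:.5f}"
        )


def surrogate_paired_test(observed, surrogate_means) -> PairedTestResult:
    """Two-sided paired Student t-test on observed minus surrogate-mean dFC.

    With n participants the test has n - 1 degrees of freedom (101
    participants give df = 100). The degenerate all-zero-difference case
    returns t = 0, p = 1; a constant non-zero difference has no within-pair
    variance and is an error.
    """
    observed = np.asarray(observed, dtype=float)
    surrogate_means = np.asarray(surrogate_means, dtype=float)
    if observed.shape != surrogate_means.shape or observed.ndim != 1:
        raise ValidationError("observed and surrogate lists must be equal-length vectors")
    n = observed.size
    if n < 2:
        raise ValidationError("paired test requires at least 2 participants")
    diff = observed - surrogate_means
    if np.std(diff, ddof=1) == 0:
        if np.allclose(diff, 0):
            return PairedTestResult(t_value=0.0, df=n - 1, p_value=1.0, mean_difference=0.0)
        raise ValidationError("zero variance of paired differences")
    t_value, p_value = stats.ttest_rel(observed, surrogate_means)
    return PairedTestResult(
        t_value=float(t_value),
        df=n - 1,
        p_value=float(p_value),
        mean_difference=float(diff.mean()),
    )
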