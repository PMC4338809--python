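"""Continuous Morlet wavelet transform and wavelet-variance temporal stability.

For a uniformly sampled redox-potential trace f(x_i) the transform at scale a
and location x_j is the discrete convolution

    W(a, x_j) = (1/a) * sum_i f(x_i) g*((x_i - x_j) / a)

with the standard complex Morlet window g(eta) = pi^(-1/4) e^(i w0 eta)
e^(-eta^2 / 2).  The per-scale wavelet variance is V(a) = (1/n) sum_j
|W(a, x_j)|^2, averaged across probes to V_t(a), then across scales to the
scalar V_t; temporal stability is its reciprocal 1/V_t.

The default prefactor is the literal 1/a (``paper_1_over_a``); the
conventional 1/sqrt(a) is available.  Each probe series is mean-centered
before transforming (switchable) so V measures fluctuation amplitude rather
than offset.  The accelerated path is an exact circular FFT correlation on a
zero-padded grid (pad >= 2n), which reproduces the literal double sum to
machine precision; no cone-of-influence masking is applied by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateStabilityError,
    DomainError,
    FormatError,
    ScaleRangeError,
)

__all__ = [
    "EhSeries",
    "ScaleGrid",
    "WaveletField",
    "WaveletVarianceResult",
    "morlet",
    "morlet_fourier_period",
    "default_scale_grid",
    "cwt",
    "scale_variance",
    "probe_mean_variance",
    "overall_variance",
    "stability",
    "treatment_stability",
    "read_eh_csv",
    "write_eh_csv",
]

OMEGA0_DEFAULT = 6.0
DT_DEFAULT = 900.0  # 15-minute sampling interval, seconds

Normalization = Literal["paper_1_over_a", "conventional_1_over_sqrt_a"]
Boundary = Literal["zero", "periodic"]


@dataclass(frozen=True)
class EhSeries:
    """One probe's uniformly sampled redox-potential trace (mV)."""

    microcosm_id: str
    probe_depth: int
    t: np.ndarray  # seconds, uniform spacing
    values: np.ndarray  # mV

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise FormatError("t and values must be 1-D arrays of equal length")
        if len(t) < 16:
            raise DomainError(f"series too short: {len(t)} samples (minimum 16)")
        if not np.all(np.isfinite(v)):
            raise FormatError("non-finite Eh values")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise FormatError("sample times must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > 1e-9 * abs(dt)):
            raise FormatError("irregular sampling: constant spacing required")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ScaleGrid:
    """Log-spaced analysis scales (same time units as the series)."""

    scales: np.ndarray
    n_voices: int

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=float)
        object.__setattr__(self, "scales", s)
        if s.ndim != 1 or len(s) == 0:
            raise DomainError("scale grid must be a non-empty 1-D array")
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise DomainError("scales must be positive and strictly increasing")

    def __len__(self) -> int:
        return len(self.scales)

    def validate_for(self, n_samples: int, dt: float) -> None:
        if self.scales[0] < 2.0 * dt - 1e-9 * dt:
            raise ScaleRangeError(f"minimum scale {self.scales[0]} below 2*dt = {2 * dt}")
        cap = n_samples * dt / 4.0
        if self.scales[-1] > cap * (1 + 1e-9):
            raise ScaleRangeError(f"maximum scale {self.scales[-1]} exceeds n*dt/4 = {cap}")


def default_scale_grid(n_samples: int, dt: float, n_voices: int = 8) -> ScaleGrid:
    """Geometric grid from 2*dt to n*dt/4 with ~n_voices scales per octave.

    Grid length is floor(octaves * n_voices) + 1 with both endpoints exact,
    so the constant consecutive ratio approximates 2^(1/n_voices).
    """
    if n_samples < 16:
        raise DomainError("n_samples must be >= 16")
    if dt <= 0:
        raise DomainError("dt must be positive")
    if n_voices < 4:
        raise DomainError("n_voices must be >= 4")
    s_min = 2.0 * dt
    s_max = n_samples * dt / 4.0
    octaves = math.log2(s_max / s_min)
    n = int(math.floor(octaves * n_voices)) + 1
    if n < 2:
        raise DomainError("scale range too narrow for a grid")
    return ScaleGrid(np.geomspace(s_min, s_max, n), n_voices)


def morlet(eta: float | np.ndarray, omega0: float = OMEGA0_DEFAULT) -> complex | np.ndarray:
    """Standard complex Morlet window pi^(-1/4) e^(i w0 eta) e^(-eta^2/2)."""
    if omega0 < 5:
        raise DomainError(f"omega0 = {omega0} violates admissibility (require >= 5)")
    eta = np.asarray(eta, dtype=float)
    out = np.pi ** (-0.25) * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
    return complex(out) if out.ndim == 0 else out


def morlet_fourier_period(scale: float | np.ndarray, omega0: float = OMEGA0_DEFAULT):
    """Equivalent Fourier period lambda = 4 pi a / (w0 + sqrt(2 + w0^2))."""
    return 4.0 * np.pi * np.asarray(scale, dtype=float) / (omega0 + math.sqrt(2.0 + omega0**2))


@dataclass(frozen=True)
class WaveletField:
    """W(a, x_j) on a scale grid x sample-time lattice."""

    grid: ScaleGrid
    locations: np.ndarray
    coefficients: np.ndarray  # complex, shape (n_scales, n_locations)
    normalization: str = "paper_1_over_a"
    omega0: float = OMEGA0_DEFAULT

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients)
        if c.shape != (len(self.grid), len(self.locations)):
            raise DomainError("coefficient block does not match grid x locations")
        if not np.all(np.isfinite(c)):
            raise DomainError("non-finite wavelet coefficients")


def _circular_kernel(n_fft: int, dt: float, scale: float, omega0: float) -> np.ndarray:
    """Morlet samples g(m*dt/a) on the FFT circle.

    The correlation identity ifft(fft(f) * conj(fft(k)))_j =
    sum_i f_i conj(k_{i-j}) supplies the conjugation of the transform formula,
    so the kernel itself is stored un-conjugated.
    """
    m = np.arange(n_fft)
    m = np.where(m <= n_fft // 2, m, m - n_fft)
    eta = m * dt / scale
    return np.pi ** (-0.25) * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)


@lru_cache(maxsize=8)
def _kernel_ffts(
    n_fft: int, dt: float, scales: tuple[float, ...], omega0: float
) -> np.ndarray:
    """conj(FFT) of the circular Morlet kernel per scale, shared across probes."""
    out = np.empty((len(scales), n_fft), dtype=complex)
    for k, a in enumerate(scales):
        out[k] = np.conj(np.fft.fft(_circular_kernel(n_fft, dt, a, omega0)))
    return out


def cwt(
    series: EhSeries,
    grid: ScaleGrid | None = None,
    normalization: Normalization = "paper_1_over_a",
    omega0: float = OMEGA0_DEFAULT,
    boundary: Boundary = "zero",
    center: bool = True,
) -> WaveletField:
    """Continuous Morlet transform of one probe series.

    ``boundary="zero"`` pads to the next power of two >= 2n (exactly the
    literal finite double sum); ``boundary="periodic"`` treats the series as
    circular, which makes V(a) invariant under time shifts of periodic input.
    """
    if omega0 < 5:
        raise DomainError(f"omega0 = {omega0} violates admissibility (require >= 5)")
    dt = series.dt
    n = series.n
    if grid is None:
        grid = default_scale_grid(n, dt)
    grid.validate_for(n, dt)

    f = series.values.astype(float)
    if center:
        f = f - f.mean()

    if boundary == "zero":
        n_fft = 1 << (2 * n - 1).bit_length()  # next pow2 >= 2n: exact linear corr
    elif boundary == "periodic":
        n_fft = n
    else:
        raise DomainError(f"unknown boundary mode {boundary!r}")

    if normalization == "paper_1_over_a":
        prefac = 1.0 / grid.scales
    elif normalization == "conventional_1_over_sqrt_a":
        prefac = 1.0 / np.sqrt(grid.scales)
    else:
        raise DomainError(f"unknown normalization {normalization!r}")

    fhat = np.fft.fft(f, n_fft)
    khat = _kernel_ffts(n_fft, dt, tuple(float(a) for a in grid.scales), omega0)
    # correlation: W_j = sum_i f_i g*((i-j) dt / a)
    coeffs = np.fft.ifft(fhat[None, :] * khat, axis=1)[:, :n] * prefac[:, None]
    return WaveletField(grid, series.t.copy(), coeffs, normalization, omega0)


def scale_variance(field: WaveletField, mode: Literal["modulus", "real"] = "modulus") -> np.ndarray:
    """V(a) = (1/n) sum_j |W(a, x_j)|^2 per scale (n = series length).

    ``mode="real"`` squares the real part instead of the modulus.
    """
    c = field.coefficients
    if c.size == 0:
        raise DomainError("empty wavelet field")
    if mode == "modulus":
        sq = np.abs(c) ** 2
    elif mode == "real":
        sq = c.real**2
    else:
        raise DomainError(f"unknown variance mode {mode!r}")
    return sq.mean(axis=1)


def probe_mean_variance(per_probe: Sequence[np.ndarray]) -> np.ndarray:
    """V_t(a): unweighted element-wise mean of per-probe V(a) curves."""
    if len(per_probe) == 0:
        raise DomainError("need at least one probe curve")
    lengths = {len(np.asarray(v)) for v in per_probe}
    if len(lengths) != 1:
        raise AlignmentError(f"probe curves on mismatched scale grids: lengths {sorted(lengths)}")
    return np.mean(np.stack([np.asarray(v, dtype=float) for v in per_probe]), axis=0)


def overall_variance(vta: np.ndarray) -> float:
    """Scalar V_t: unweighted mean of V_t(a) over the scale grid."""
    vta = np.asarray(vta, dtype=float)
    if vta.size == 0:
        raise DomainError("empty variance curve")
    if np.any(vta < 0):
        raise DomainError("variance curve has negative entries")
    return float(vta.mean())


def stability(vt: float) -> float:
    """Temporal stability 1/V_t; V_t = 0 is flagged, never silently divided."""
    if vt < 0:
        raise DomainError(f"V_t must be non-negative, got {vt}")
    if vt == 0:
        raise DegenerateStabilityError("V_t = 0: perfectly constant signal, stability infinite")
    return 1.0 / vt


@dataclass(frozen=True)
class WaveletVarianceResult:
    """Per-scale and aggregate wavelet variance for one treatment/microcosm."""

    grid: ScaleGrid
    per_probe: tuple[np.ndarray, ...]  # V(a) per probe
    probe_mean: np.ndarray  # V_t(a)
    overall: float  # V_t
    stability: float  # 1/V_t (inf when degenerate)
    degenerate: bool
    normalization: str
    probe_depths: tuple[int, ...]


def treatment_stability(
    series_set: Iterable[EhSeries],
    grid: ScaleGrid | None = None,
    normalization: Normalization = "paper_1_over_a",
    omega0: float = OMEGA0_DEFAULT,
    boundary: Boundary = "zero",
    center: bool = True,
    mode: Literal["modulus", "real"] = "modulus",
) -> WaveletVarianceResult:
    """cwt -> V(a) per probe -> V_t(a) -> V_t -> 1/V_t for a set of probes."""
    series_list = list(series_set)
    if not series_list:
        raise DomainError("need at least one Eh series")
    n0, dt0 = series_list[0].n, series_list[0].dt
    for s in series_list[1:]:
        if s.n != n0 or abs(s.dt - dt0) > 1e-9 * dt0:
            raise AlignmentError("all probe series must share length and sampling interval")
    if grid is None:
        grid = default_scale_grid(n0, dt0)
    curves = []
    for s in series_list:
        field = cwt(s, grid, normalization=normalization, omega0=omega0,
                    boundary=boundary, center=center)
        curves.append(scale_variance(field, mode=mode))
    vta = probe_mean_variance(curves)
    vt = overall_variance(vta)
    try:
        stab = stability(vt)
        degenerate = False
    except DegenerateStabilityError:
        stab = math.inf
        degenerate = True
    return WaveletVarianceResult(
        grid=grid,
        per_probe=tuple(curves),
        probe_mean=vta,
        overall=vt,
        stability=stab,
        degenerate=degenerate,
        normalization=normalization,
        probe_depths=tuple(s.probe_depth for s in series_list),
    )


def read_eh_csv(path: str | Path) -> dict[str, list[EhSeries]]:
    """Read long-format Eh CSV -> {microcosm_id: [EhSeries per probe]}.

    Expected columns: microcosm_id, probe_depth_mm, time_s, eh_mV.
    """
    df = pd.read_csv(path)
    required = {"microcosm_id", "probe_depth_mm", "time_s", "eh_mV"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"Eh CSV missing columns: {sorted(missing)}")
    out: dict[str, list[EhSeries]] = {}
    for (mc, depth), g in df.groupby(["microcosm_id", "probe_depth_mm"], sort=True):
        g = g.sort_values("time_s")
        out.setdefault(str(mc), []).append(
            EhSeries(str(mc), int(depth), g["time_s"].to_numpy(), g["eh_mV"].to_numpy())
        )
    return out


def write_eh_csv(series_by_microcosm: dict[str, list[EhSeries]], path: str | Path) -> None:
    frames = []
    for mc in sorted(series_by_microcosm):
        for s in series_by_microcosm[mc]:
            frames.append(
                pd.DataFrame(
                    {
                        "microcosm_id": s.microcosm_id,
                        "probe_depth_mm": s.probe_depth,
                        "time_s": s.t,
                        "eh_mV": s.values,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
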