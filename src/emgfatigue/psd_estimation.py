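"""One-sided PSD estimation: Welch averaged periodograms and Burg AR.

Both estimators are implemented from first principles so that every
normalization and segmentation choice is explicit and testable:

* Welch — the signal is split into overlapping segments of 25% of its
  length, advanced by 25% of the segment (75% overlap), which yields 13
  segments for every signal length; each segment is tapered (Tukey window),
  zero-padded to the full signal length, and the window-power-normalized
  periodograms are averaged.

* Burg — the stage-wise lattice recursion: each reflection coefficient
  minimizes the summed forward and backward squared prediction error, and
  prediction coefficients are updated by the Levinson–Durbin step.  The
  spectrum is sigma^2 / (f_s |A(f)|^2) with A the prediction polynomial.

Both return the same frequency grid (spacing f_s/N) so estimates can be
compared line by line.  PSDs use the one-sided density convention
(power per Hz, interior lines doubled); mean/median frequency are invariant
to the overall scale either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "PsdEstimate",
    "WelchConfig",
    "ArModel",
    "segment_signal",
    "modified_periodogram",
    "welch_psd",
    "burg_fit",
    "burg_psd",
]


@dataclass(frozen=True)
class PsdEstimate:
    """A one-sided PSD on a frequency grid with estimator provenance."""

    grid: np.ndarray  # Hz, 0 .. f_s/2
    values: np.ndarray  # power / Hz, >= 0
    method: str  # "welch" | "burg<p>" | "periodogram" | "ideal"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ValueError("grid and values must have the same length")

    @property
    def df(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def total_power(self) -> float:
        """Integrated one-sided power (rectangle rule on the line grid)."""
        return float(np.sum(self.values) * self.df)


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings.

    window_fraction / step_fraction default to 0.25/0.25: segments of 25%
    of the signal advanced by 25% of the segment, i.e. 75% overlap and 13
    segments at any length.  Each segment is zero-padded to the full signal
    length so the grid spacing is f_s/N.  ``detrend`` removes each
    segment's mean before tapering.
    """

    window: str = "tukey"
    tukey_alpha: float = 0.5
    window_fraction: float = 0.25
    step_fraction: float = 0.25
    detrend: bool = True

    def make_window(self, m: int) -> np.ndarray:
        if self.window == "tukey":
            return sps.windows.tukey(m, self.tukey_alpha)
        return sps.get_window(self.window, m, fftbins=False)


def segment_signal(
    x: np.ndarray,
    window_fraction: float = 0.25,
    step_fraction: float = 0.25,
) -> list[np.ndarray]:
    """Split ``x`` into overlapping segments fully inside the signal.

    Segment length M = round(window_fraction*N); hop = round(step_fraction*M);
    starts at 0, hop, 2*hop, ... while start+M <= N.  With the defaults this
    gives floor((N-M)/hop)+1 = 13 segments for every N divisible enough.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = int(round(window_fraction * n))
    if m < 8:
        raise ValueError("segment length below 8 samples; signal too short")
    hop = int(round(step_fraction * m))
    if hop == 0:
        raise ValueError("hop of zero samples: step fraction too small")
    return [x[s : s + m] for s in range(0, n - m + 1, hop)]


def modified_periodogram(
    segment: np.ndarray,
    window: np.ndarray,
    nfft: int,
    f_s: float,
) -> PsdEstimate:
    """Window-power-normalized one-sided periodogram of one segment.

    ``|DFT(w*x, nfft)|^2 / (M * U * f_s)`` with ``U = mean(w^2)`` so that a
    rectangular window (U=1) reduces to the raw periodogram; interior lines
    are doubled for the one-sided density convention.
    """
    segment = np.asarray(segment, dtype=float)
    window = np.asarray(window, dtype=float)
    m = len(segment)
    if len(window) != m:
        raise ValueError("window and segment lengths differ")
    u = float(np.mean(window**2))
    if u == 0:
        raise ValueError("all-zero window")
    if nfft < m:
        raise ValueError("nfft must be at least the segment length")
    spec = np.fft.rfft(window * segment, n=nfft)
    psd = np.abs(spec) ** 2 / (m * u * f_s)
    psd = _one_sided(psd, nfft)
    grid = np.fft.rfftfreq(nfft, d=1.0 / f_s)
    return PsdEstimate(
        grid=grid, values=psd, method="periodogram", meta={"M": m, "U": u}
    )


def _one_sided(psd: np.ndarray, nfft: int) -> np.ndarray:
    psd = psd.copy()
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    return psd


def welch_psd(
    x: np.ndarray,
    f_s: float,
    config: WelchConfig | None = None,
    nfft: int | None = None,
) -> PsdEstimate:
    """Welch estimate: average of the segment periodograms.

    Each segment is zero-padded to ``nfft`` (default: the full signal
    length), so the estimate lives on the same grid as a length-N transform.
    """
    config = config or WelchConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    nfft = n if nfft is None else nfft
    segments = segment_signal(x, config.window_fraction, config.step_fraction)
    m = len(segments[0])
    window = config.make_window(m)
    acc = np.zeros(nfft // 2 + 1)
    for seg in segments:
        if config.detrend:
            seg = seg - seg.mean()
        acc += modified_periodogram(seg, window, nfft, f_s).values
    values = acc / len(segments)
    grid = np.fft.rfftfreq(nfft, d=1.0 / f_s)
    return PsdEstimate(
        grid=grid,
        values=values,
        method="welch",
        meta={
            "segments": len(segments),
            "M": m,
            "window": config.window,
            "tukey_alpha": config.tukey_alpha,
            "nfft": nfft,
        },
    )


@dataclass(frozen=True)
class ArModel:
    """Autoregressive model fitted by the Burg lattice recursion.

    ``prediction_coefficients`` are (a_1 .. a_p) in the convention
    ``x̂(n) = -sum_z a_z x(n-z)``; ``reflection_coefficients`` holds the
    per-stage lattice coefficients (the last prediction coefficient of each
    stage); ``error_variance`` is the final prediction-error power and
    ``error_path`` its non-increasing per-stage history.
    """

    order: int
    prediction_coefficients: np.ndarray
    reflection_coefficients: np.ndarray
    error_variance: float
    error_path: np.ndarray

    @property
    def polynomial(self) -> np.ndarray:
        """Full prediction polynomial [1, a_1, ..., a_p]."""
        return np.concatenate([[1.0], self.prediction_coefficients])


def burg_fit(x: np.ndarray, order: int) -> ArModel:
    """Fit an AR(p) model by the Burg method.

    At stage m the reflection coefficient

        k_m = -2 * sum(f_m-1[n] * b_m-1[n-1]) /
                   sum(f_m-1[n]^2 + b_m-1[n-1]^2)

    minimizes the summed forward+backward squared prediction error (a
    closed-form least-squares solution, so |k_m| <= 1 and the model is
    stable); the prediction coefficients follow from the Levinson–Durbin
    update and the error power shrinks by (1 - k_m^2) per stage.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= n:
        raise ValueError("order must be smaller than the signal length")
    if np.allclose(x, x[0]):
        raise ValueError("constant signal: prediction error is degenerate")

    fwd = x.copy()
    bwd = x.copy()
    a = np.array([1.0])
    err = float(np.dot(x, x)) / n
    path = [err]
    refl = []
    for _ in range(order):
        f1 = fwd[1:]
        b1 = bwd[:-1]
        denom = float(np.dot(f1, f1) + np.dot(b1, b1))
        if denom == 0.0:
            raise ValueError("degenerate stage: zero prediction-error energy")
        k = -2.0 * float(np.dot(f1, b1)) / denom
        refl.append(k)
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        fwd, bwd = f1 + k * b1, b1 + k * f1
        err *= 1.0 - k * k
        path.append(err)
    return ArModel(
        order=order,
        prediction_coefficients=a[1:],
        reflection_coefficients=np.array(refl),
        error_variance=err,
        error_path=np.array(path),
    )


def burg_psd(
    model: ArModel,
    f_s: float,
    nfft: int,
) -> PsdEstimate:
    """One-sided AR spectrum sigma^2 / (f_s |A(f)|^2) on the length-nfft grid.

    ``nfft`` should equal the signal length used for the fit so the grid
    matches the Welch estimate line for line.
    """
    grid = np.fft.rfftfreq(nfft, d=1.0 / f_s)
    z = np.exp(-2j * np.pi * np.outer(grid, np.arange(model.order + 1)) / f_s)
    denom = np.abs(z @ model.polynomial) ** 2
    psd = model.error_variance / (f_s * denom)
    psd = _one_sided(psd, nfft)
    return PsdEstimate(
        grid=grid,
        values=psd,
        method=f"burg{model.order}",
        meta={
            "order": model.order,
            "error_variance": model.error_variance,
            "nfft": nfft,
        },
    )
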