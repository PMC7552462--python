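"""Spectral preprocessing: SNV, polynomial detrend, Savitzky-Golay derivatives.

The calibration experiment compares four variants, each expressed as an
ordered :class:`PreprocessSpec`:

* raw (no steps)
* SNV + detrend
* first derivative
* first derivative + SNV + detrend (derivative applied first)

SNV (standard normal variate) standardizes each spectrum to mean 0 and
unit sample standard deviation over the wavelength axis, compensating
multiplicative scatter from particle-size variation. Detrending removes
a per-spectrum least-squares polynomial of the wavelength (order 2 by
default, the classical SNV-detrend pairing). Derivatives are
Savitzky-Golay local-polynomial derivatives with respect to wavelength,
in per-nm units, computed on the full grid with truncated-window
polynomial fits at the edges so loading vectors stay aligned with the
grid (edge trimming is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateInputError
from .spectra_io import SpectrumSet, WavelengthGrid

__all__ = [
    "PreprocessSpec",
    "snv",
    "detrend",
    "derivative",
    "apply_pipeline",
    "STANDARD_VARIANTS",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """An ordered list of preprocessing steps.

    Each step is either ``("snv",)``, ``("detrend", order)`` or
    ``("derivative", order, window, polyorder)``. An empty list means raw
    spectra. The spec serializes to/from a compact string such as
    ``"derivative:1:11:2|snv|detrend:2"`` for config files.
    """

    steps: tuple[tuple, ...] = ()
    label: str = "raw"

    def __post_init__(self) -> None:
        for step in self.steps:
            kind = step[0]
            if kind == "snv":
                continue
            if kind == "detrend":
                if step[1] < 0:
                    raise ValueError("detrend order must be >= 0")
            elif kind == "derivative":
                order, window, polyorder = step[1], step[2], step[3]
                if order not in (1, 2):
                    raise ValueError("derivative order must be 1 or 2")
                if window % 2 == 0 or window <= polyorder:
                    raise ValueError("window must be odd and > polyorder")
                if polyorder < order:
                    raise ValueError("polyorder must be >= derivative order")
            else:
                raise ValueError(f"unknown preprocessing step {kind!r}")

    def serialize(self) -> str:
        if not self.steps:
            return "raw"
        return "|".join(":".join(str(x) for x in step) for step in self.steps)

    @classmethod
    def parse(cls, text: str, label: str | None = None) -> "PreprocessSpec":
        text = text.strip()
        if text in ("", "raw"):
            return cls((), label or "raw")
        steps = []
        for token in text.split("|"):
            parts = token.split(":")
            kind = parts[0]
            if kind == "snv":
                steps.append(("snv",))
            elif kind == "detrend":
                steps.append(("detrend", int(parts[1]) if len(parts) > 1 else 2))
            elif kind == "derivative":
                order = int(parts[1]) if len(parts) > 1 else 1
                window = int(parts[2]) if len(parts) > 2 else 11
                poly = int(parts[3]) if len(parts) > 3 else (2 if order == 1 else 3)
                steps.append(("derivative", order, window, poly))
            else:
                raise ValueError(f"unknown preprocessing step {kind!r}")
        return cls(tuple(steps), label or text)


def _as_matrix(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def snv(values: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """Standard normal variate: per-spectrum standardization to mean 0, sd 1.

    Uses the sample (n-1 denominator) standard deviation. Raises
    :class:`DegenerateInputError` naming the offending sample for
    constant spectra.
    """
    mat, squeeze = _as_matrix(values)
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    # relative floor: a numerically constant row has sd at rounding level
    bad = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))
    if bad.size:
        name = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise DegenerateInputError(f"constant spectrum (sd = 0) for sample {name}")
    out = (mat - mean[:, None]) / sd[:, None]
    return out[0] if squeeze else out


def detrend(
    values: np.ndarray, grid: WavelengthGrid | np.ndarray, order: int = 2
) -> np.ndarray:
    """Residual of a per-spectrum least-squares polynomial in wavelength."""
    if order < 0:
        raise ValueError("detrend order must be >= 0")
    mat, squeeze = _as_matrix(values)
    lam = grid.points if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    if lam.size <= order + 1:
        raise ValueError(f"grid of {lam.size} points cannot fit order-{order} trend")
    # centre/scale wavelength for conditioning; residual is basis-invariant
    x = (lam - lam.mean()) / lam.std()
    V = np.vander(x, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, mat.T, rcond=None)
    out = mat - (V @ coef).T
    return out[0] if squeeze else out


def derivative(
    spectra: SpectrumSet,
    order: int = 1,
    window: int = 11,
    polyorder: int | None = None,
    trim_edges: bool = False,
) -> SpectrumSet:
    """Savitzky-Golay derivative with respect to wavelength (per-nm units).

    Defaults: 11-point window (55 nm at 5 nm spacing), polynomial order 2
    for first derivatives and 3 for second. Edges are handled by fitting
    the local polynomial within truncated windows (``mode="interp"``) so
    the output grid equals the input grid; ``trim_edges`` zeroes the
    half-window margin instead for inspection of interior-only behaviour.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if polyorder is None:
        polyorder = 2 if order == 1 else 3
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > spectra.p:
        raise ValueError(f"window {window} exceeds grid size {spectra.p}")
    if polyorder < order or polyorder >= window:
        raise ValueError("need order <= polyorder < window")
    out = savgol_filter(
        spectra.matrix,
        window_length=window,
        polyorder=polyorder,
        deriv=order,
        delta=spectra.grid.step,
        axis=1,
        mode="interp",
    )
    if trim_edges:
        half = window // 2
        out[:, :half] = 0.0
        out[:, -half:] = 0.0
    return spectra.copy_with(out)


def apply_pipeline(spectra: SpectrumSet, spec: PreprocessSpec) -> SpectrumSet:
    """Apply the steps of ``spec`` in listed order; an empty spec is the identity."""
    current = spectra
    for step in spec.steps:
        kind = step[0]
        if kind == "snv":
            current = current.copy_with(snv(current.matrix, current.ids))
        elif kind == "detrend":
            current = current.copy_with(detrend(current.matrix, current.grid, step[1]))
        elif kind == "derivative":
            current = derivative(current, order=step[1], window=step[2], polyorder=step[3])
    return current


def _standard_variants() -> dict[str, PreprocessSpec]:
    d1 = ("derivative", 1, 11, 2)
    return {
        "raw": PreprocessSpec((), "raw"),
        "snv_detrend": PreprocessSpec((("snv",), ("detrend", 2)), "snv_detrend"),
        "deriv1": PreprocessSpec((d1,), "deriv1"),
        "deriv1_snv_detrend": PreprocessSpec(
            (d1, ("snv",), ("detrend", 2)), "deriv1_snv_detrend"
        ),
    }


#: The four preprocessing variants of the calibration experiment, keyed by label.
STANDARD_VARIANTS: dict[str, PreprocessSpec] = _standard_variants()
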