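"""Synthetic NIR spectra and reference chemistry with realistic structure.

The generator emulates the statistical shape of a 92-sample cabbage and
Brussels sprout NIR dataset: right-skewed fresh-weight glucobrassicin
(GBS) concentrations (lognormal, mean 65.16 and sd 80.01 µmol·100 g⁻¹,
clipped to the observed range 3.69-379.16), dry-matter fractions around
0.122 linking the fresh- and dry-weight bases, two replicate scans per
sample, and absorbance spectra on the 950-1650 nm / 5 nm grid built
from Beer-Lambert Gaussian constituent bands.

The spectral model for one scan is

    A(λ) = (1 + m) · Σ_k c_k G_k(λ) + baseline(λ) + ε(λ)

with Gaussian bands G_k, a per-scan multiplicative scatter factor
m ~ N(0, scatter_sd) acting on the chemical signal (the artifact SNV is
meant to remove), a fixed quadratic baseline (the artifact detrending
removes), and i.i.d. channel noise ε ~ N(0, noise_sd). The default band
library puts the GBS band at 1450 nm — deliberately overlapped by a
water/O-H band, as in real leaf-tissue spectra where the indole N-H
first-overtone region also carries moisture bands — plus a second water
band at 1420 nm and two interfering constituents at 1200 and 1550 nm
with random concentrations.

All randomness flows from the single ``seed`` through one named
generator; outputs are deterministic per seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra_io import (
    ReferenceTable,
    SpectrumSet,
    WavelengthGrid,
    write_reference,
    write_spectra,
)

__all__ = ["Band", "SyntheticConfig", "generate_reference", "generate_spectra",
           "generate_dataset"]


@dataclass(frozen=True)
class Band:
    """A Gaussian absorption band: amplitude per unit concentration."""

    center: float  # nm
    width: float  # Gaussian sigma, nm
    amplitude: float  # absorbance per unit concentration at the band centre
    constituent: str  # {gbs, water, interferent_1, interferent_2, ...}


def _default_bands() -> tuple[Band, ...]:
    return (
        # GBS: indole N-H first-overtone region; amplitude per µmol·100 g⁻¹
        Band(1450.0, 25.0, 8.0e-4, "gbs"),
        # water O-H first overtones, overlapping the GBS band
        Band(1420.0, 30.0, 0.15, "water"),
        Band(1450.0, 40.0, 0.10, "water"),
        # unrelated constituents with their own concentration variation
        Band(1200.0, 35.0, 0.08, "interferent_1"),
        Band(1550.0, 45.0, 0.08, "interferent_2"),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults for the synthetic dataset.

    The reference-distribution targets (n=92, lognormal mean 65.16,
    sd 80.01, range [3.69, 379.16] µmol·100 g⁻¹ fresh weight; mean
    dry-matter fraction 0.122) reproduce the published summary statistics
    of the calibration population; two replicate scans per sample give
    184 scans averaging to 92 spectra.
    """

    n_samples: int = 92
    n_replicates: int = 2
    fresh_mean: float = 65.16  # µmol GBS · 100 g⁻¹ fresh weight
    fresh_sd: float = 80.01
    fresh_range: tuple[float, float] = (3.69, 379.16)
    dm_mean: float = 0.122  # dry-matter fraction
    dm_sd: float = 0.02
    band_library: tuple[Band, ...] = field(default_factory=_default_bands)
    baseline_coeffs: tuple[float, float, float] = (0.2, 1.5e-4, 5.0e-8)
    scatter_sd: float = 0.05  # multiplicative, on the chemical signal
    noise_sd: float = 0.002  # absorbance units, per channel
    fresh_distribution: str = "lognormal"  # or "truncated_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.fresh_sd < 0 or self.dm_sd < 0 or self.scatter_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        grid = WavelengthGrid()
        for band in self.band_library:
            if not grid.start <= band.center <= grid.stop:
                raise ValueError(
                    f"band centre {band.center} nm outside grid "
                    f"[{grid.start}, {grid.stop}]"
                )


_DM_BOUNDS = (0.05, 0.30)


def _lognormal_params_truncated(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """(mu, sigma) such that the lognormal truncated to [lo, hi] has the
    requested mean and sd.

    Matching the truncated moments (rather than the parent's) keeps the
    rejection-clipped sample centred on the targets even though clipping
    shaves the upper tail. Solved from the lognormal partial moments
    E[X^k; lo<X<hi] = exp(k*mu + k^2 sigma^2/2) * (Phi(b-k*sigma) - Phi(a-k*sigma)).
    """
    from scipy import optimize, stats

    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal needs fresh_mean > 0 and fresh_sd > 0")

    def trunc_moments(mu: float, sigma: float) -> tuple[float, float]:
        a = (np.log(lo) - mu) / sigma
        b = (np.log(hi) - mu) / sigma
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        if z <= 0:
            return np.inf, np.inf
        def pm(k: int) -> float:
            return float(
                np.exp(k * mu + k * k * sigma * sigma / 2)
                * (stats.norm.cdf(b - k * sigma) - stats.norm.cdf(a - k * sigma))
                / z
            )
        m1, m2 = pm(1), pm(2)
        return m1, np.sqrt(max(m2 - m1 * m1, 0.0))

    def resid(p: np.ndarray) -> list[float]:
        m1, s1 = trunc_moments(p[0], p[1])
        return [m1 - mean, s1 - sd]

    sigma2 = np.log1p((sd / mean) ** 2)
    x0 = [np.log(mean) - sigma2 / 2, np.sqrt(sigma2)]
    sol = optimize.least_squares(resid, x0, bounds=([-20.0, 1e-4], [20.0, 8.0]))
    m1, s1 = trunc_moments(*sol.x)
    if abs(m1 - mean) > 1e-3 * mean or abs(s1 - sd) > 1e-3 * sd:
        raise ValueError(
            f"no lognormal truncated to {lo}-{hi} has mean {mean} and sd {sd}"
        )
    return float(sol.x[0]), float(sol.x[1])


def _draw_fresh(rng: np.random.Generator, config: SyntheticConfig, n: int) -> np.ndarray:
    lo, hi = config.fresh_range
    m, s = config.fresh_mean, config.fresh_sd
    if config.fresh_distribution == "lognormal":
        mu, sigma = _lognormal_params_truncated(m, s, lo, hi)
        draw = lambda k: rng.lognormal(mu, sigma, k)  # noqa: E731
    elif config.fresh_distribution == "truncated_normal":
        draw = lambda k: rng.normal(m, s, k)  # noqa: E731
    else:
        raise ValueError(f"unknown fresh_distribution {config.fresh_distribution!r}")
    out = np.empty(0)
    # rejection-clip to the observed concentration range
    for _ in range(1000):
        batch = draw(max(n, 64))
        out = np.concatenate([out, batch[(batch >= lo) & (batch <= hi)]])
        if out.size >= n:
            return out[:n]
    raise ValueError("could not draw fresh-weight values inside fresh_range")


def _draw_dm(rng: np.random.Generator, config: SyntheticConfig, n: int) -> np.ndarray:
    if config.dm_sd == 0:
        return np.full(n, config.dm_mean)
    out = np.empty(0)
    lo, hi = _DM_BOUNDS
    for _ in range(1000):
        batch = rng.normal(config.dm_mean, config.dm_sd, max(n, 64))
        out = np.concatenate([out, batch[(batch > lo) & (batch < hi)]])
        if out.size >= n:
            return out[:n]
    raise ValueError("could not draw dry-matter fractions inside (0.05, 0.30)")


def _rng_for(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # stable across processes (python str hash is salted)
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng([config.seed, tag])


def generate_reference(config: SyntheticConfig) -> ReferenceTable:
    """Draw per-sample GBS reference chemistry.

    Fresh-weight GBS is lognormal parameterized to hit the configured
    mean/sd, rejection-clipped to ``fresh_range``; dry-matter fraction is
    normal truncated to (0.05, 0.30); the dry-weight value follows as
    gbs_fresh / (100 * dm). Deterministic per seed.
    """
    rng = _rng_for(config, "reference")
    n = config.n_samples
    ids = [f"S{i + 1:03d}" for i in range(n)]
    if n == 0:
        return ReferenceTable(ids, np.empty(0), np.empty(0), np.empty(0))
    fresh = _draw_fresh(rng, config, n)
    dm = _draw_dm(rng, config, n)
    dry = fresh / (100.0 * dm)
    return ReferenceTable(ids, fresh, dry, dm)


def _constituent_concentrations(
    rng: np.random.Generator, reference: ReferenceTable, config: SyntheticConfig
) -> dict[str, np.ndarray]:
    """Per-sample concentrations for every constituent in the band library."""
    n = reference.n
    conc: dict[str, np.ndarray] = {"gbs": reference.gbs_fresh}
    names = {b.constituent for b in config.band_library} - {"gbs"}
    for name in sorted(names):
        if name == "water":
            # residual moisture of freeze-dried powder: nearly constant
            conc[name] = rng.normal(1.0, 0.03, n).clip(min=0.5)
        else:
            conc[name] = rng.uniform(0.2, 1.0, n)
    return conc


def generate_spectra(reference: ReferenceTable, config: SyntheticConfig) -> SpectrumSet:
    """Simulate replicate absorbance scans for every reference sample.

    Returns ``n_samples * n_replicates`` scans whose ids repeat each
    sample id once per replicate, matching an instrument export where the
    same sample is scanned repeatedly.
    """
    grid = WavelengthGrid()
    lam = grid.points
    rng = _rng_for(config, "spectra")
    conc = _constituent_concentrations(rng, reference, config)
    a0, a1, a2 = config.baseline_coeffs
    baseline = a0 + a1 * lam + a2 * lam**2
    n, r = reference.n, config.n_replicates
    ids: list[str] = []
    rows = np.empty((n * r, grid.size))
    for i in range(n):
        signal = np.zeros(grid.size)
        for band in config.band_library:
            g = np.exp(-((lam - band.center) ** 2) / (2 * band.width**2))
            signal += conc[band.constituent][i] * band.amplitude * g
        for j in range(r):
            m = rng.normal(0.0, config.scatter_sd) if config.scatter_sd > 0 else 0.0
            eps = rng.normal(0.0, config.noise_sd, grid.size) if config.noise_sd > 0 else 0.0
            rows[i * r + j] = (1.0 + m) * signal + baseline + eps
            ids.append(reference.ids[i])
    return SpectrumSet(grid, ids, rows)


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[SpectrumSet, ReferenceTable]:
    """One-call fixture: reference table + replicate scans from a shared seed.

    When ``out_dir`` is given, writes ``spectra.csv`` (raw scans, one row
    per scan) and ``reference.csv`` in the canonical dialects;
    byte-identical across repeated calls with the same config.
    """
    reference = generate_reference(config)
    scans = generate_spectra(reference, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        # scan ids repeat per replicate; disambiguate for the unique-id dialect
        export = SpectrumSet(
            scans.grid,
            [f"{sid}_r{k % config.n_replicates + 1}" for k, sid in enumerate(scans.ids)],
            scans.matrix,
        )
        write_spectra(export, out_dir / "spectra.csv")
        write_reference(reference, out_dir / "reference.csv")
    return scans, reference
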