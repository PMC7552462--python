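"""Calibration metrics (R², RMSE, RPD), screening bands, stratified splitting.

RPD — the ratio of (performance to) deviation — divides the standard
deviation of the reference-method values by the root mean squared error
of prediction. The conventional screening bands are: RPD < 2.0 not
useful; 2.0 <= RPD < 3.0 acceptable for qualitative screening into
high/medium/low groups; RPD >= 3.0 excellent for quantification.
By default the reference sd is that of the full sample set (not the
held-out subset); the sd source is a caller choice via the argument.

The train/test split stratifies on the response: samples are binned by
response quantiles and test samples drawn proportionally from each bin
(largest-remainder rounding), which keeps the held-out set
representative of a right-skewed concentration distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AllocationError, DegenerateInputError
from .spectra_io import ReferenceTable

__all__ = [
    "ModelMetrics",
    "SplitResult",
    "r_squared",
    "rmse",
    "rpd",
    "classify_rpd",
    "stratified_split",
]


@dataclass
class ModelMetrics:
    """One row of a calibration-experiment results table."""

    basis: str  # {fresh, dry}
    preprocessing: str  # PreprocessSpec label
    r2_cal: float
    rmsec: float
    r2_cv: float
    rmsep: float
    rpd: float
    terms: int

    def __post_init__(self) -> None:
        if self.rmsec < 0 or self.rmsep < 0 or self.rpd <= 0:
            raise ValueError("rmsec/rmsep must be >= 0 and rpd > 0")
        if self.r2_cal > 1 or self.r2_cv > 1:
            raise ValueError("r2 cannot exceed 1")


@dataclass
class SplitResult:
    """A deterministic stratified partition of sample ids."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    n_bins: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot about mean(y_true)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("y_true is constant; R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size == 0:
        raise ValueError("need at least 1 observation")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def rpd(sd_reference: float, rmsep: float) -> float:
    """Ratio of reference-method standard deviation to prediction error."""
    if sd_reference <= 0 or rmsep <= 0:
        raise ValueError("sd_reference and rmsep must be > 0")
    return sd_reference / rmsep


def classify_rpd(value: float) -> str:
    """Band an RPD into {not_useful, screening, quantification}.

    Boundaries are closed on the left: [2.0, 3.0) screens, >= 3.0
    quantifies. (The 2.5-3.0 gap between the conventional "2.0-2.5
    screening" and ">3.0 excellent" bands is assigned to screening.)
    """
    if value <= 0:
        raise ValueError("rpd must be > 0")
    if value < 2.0:
        return "not_useful"
    if value < 3.0:
        return "screening"
    return "quantification"


def stratified_split(
    reference: ReferenceTable,
    basis: str = "fresh",
    n_test: int = 24,
    n_bins: int = 4,
    seed: int = 0,
) -> SplitResult:
    """Quantile-stratified random train/test split on the response.

    Samples are ranked by the chosen response and cut into ``n_bins``
    quantile strata; ``n_test`` test samples are allocated proportionally
    to stratum size (largest-remainder rounding) and drawn uniformly
    within each stratum using ``numpy.random.default_rng(seed)``.
    ``n_bins=1`` degenerates to a simple random split.
    """
    n = reference.n
    if not 0 < n_test < n:
        raise ValueError(f"n_test must be in (0, {n})")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    y = reference.values(basis)
    rng = np.random.default_rng(seed)
    # quantile bin edges; ranks avoid ties collapsing bins
    order = np.argsort(y, kind="stable")
    strata = [order[i * n // n_bins : (i + 1) * n // n_bins] for i in range(n_bins)]
    strata = [s for s in strata if s.size]
    sizes = np.array([s.size for s in strata])
    exact = n_test * sizes / n
    alloc = np.floor(exact).astype(int)
    remainder = n_test - alloc.sum()
    if remainder > 0:
        frac_order = np.argsort(-(exact - alloc), kind="stable")
        alloc[frac_order[:remainder]] += 1
    for s, a in zip(strata, alloc):
        if a > s.size:
            raise AllocationError(
                f"stratum of {s.size} samples cannot supply {a} test samples; "
                f"use fewer bins"
            )
    test_idx: list[int] = []
    for s, a in zip(strata, alloc):
        test_idx.extend(rng.choice(s, size=a, replace=False).tolist())
    test_set = set(test_idx)
    train_ids = [reference.ids[i] for i in range(n) if i not in test_set]
    test_ids = [reference.ids[i] for i in sorted(test_set)]
    return SplitResult(train_ids=train_ids, test_ids=test_ids, seed=seed, n_bins=n_bins)
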