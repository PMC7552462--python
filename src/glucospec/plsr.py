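"""NIPALS PLS1 regression, leave-one-out cross-validation, one-sigma selection.

PLS1 extracts latent components t_a = X w_a maximizing covariance with a
single response, deflating X after each component. The NIPALS recursion
for one response needs no inner iteration:

    w_a = X_a' y_a / ||X_a' y_a||      (weights)
    t_a = X_a w_a                      (scores)
    p_a = X_a' t_a / (t_a' t_a)        (x-loadings)
    q_a = y_a' t_a / (t_a' t_a)        (y-loading)
    X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a

Regression coefficients on the centred/scaled variables are
b* = W (P'W)^{-1} q, back-transformed to the original measurement scale.
Predictors and response are mean-centred, and optionally scaled to unit
variance (``scale=True``, the default, mirroring classical chemometrics
"autoscaling"); centre-only is one flag away.

Model size is chosen by leave-one-out cross-validation with the
one-sigma heuristic: the fewest components whose RMSECV is within one
standard error of the minimum RMSECV. The zero-component model (predict
the training mean) is a legal fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateInputError

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_plsr",
    "predict",
    "loo_cv",
    "select_ncomp_one_sigma",
    "get_loadings",
    "save_model",
    "load_model",
]


@dataclass
class PLSModel:
    """A fitted PLS1 calibration.

    Coefficients and intercept act on raw (uncentred, unscaled) predictor
    rows: ``yhat = X @ coef + intercept``. Weights, loadings and scores
    live on the centred/scaled scale.
    """

    x_center: np.ndarray  # (p,)
    x_scale: np.ndarray  # (p,) ones when scale off
    y_center: float
    y_scale: float
    weights: np.ndarray  # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    coef: np.ndarray  # (p,), original variable scale
    intercept: float
    ncomp: int
    scale: bool
    scores: np.ndarray | None = None  # (n, A) training scores

    @property
    def p(self) -> int:
        return self.coef.size


@dataclass
class CVResult:
    """Leave-one-out CV error curve over candidate component counts 0..max_ncomp.

    ``rmsecv[a]`` is the root mean squared LOO error with ``a`` components;
    ``se[a]`` is its standard error, obtained from the standard error of
    the mean per-sample squared error via the delta method
    (se_rmse = se_mse / (2 * rmse)).
    """

    rmsecv: np.ndarray
    se: np.ndarray
    chosen_ncomp: int
    press_residuals: np.ndarray | None = None  # (n, max_ncomp+1) LOO residuals


def _center_scale(X: np.ndarray, y: np.ndarray, scale: bool):
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(x_scale == 0)
        if zero.size:
            raise DegenerateInputError(
                f"zero-variance predictor column(s) at index {zero.tolist()} with scale on"
            )
        y_scale = float(y.std(ddof=1))
        if y_scale == 0:
            y_scale = 1.0
    else:
        x_scale = np.ones(X.shape[1])
        y_scale = 1.0
    return x_center, x_scale, y_center, y_scale


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, ncomp: int):
    """NIPALS PLS1 on centred (and scaled) data; returns W, P, q, T."""
    n, p = Xc.shape
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    X, y = Xc.copy(), yc.copy()
    for a in range(ncomp):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:  # response fully deflated; remaining components are null
            break
        w /= norm
        t = X @ w
        tt = t @ t
        if tt == 0:
            break
        pa = X.T @ t / tt
        qa = y @ t / tt
        X = X - np.outer(t, pa)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
    return W, P, q, T


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Coefficient vectors on the centred/scaled scale for every ncomp 1..A.

    Uses the bidiagonal structure of R = P'W: solves the triangular system
    incrementally so the full path costs little more than one solve.
    """
    p, A = W.shape
    path = np.zeros((p, A))
    R = P.T @ W  # unit upper triangular in exact arithmetic
    # solve R alpha = q progressively: alpha = R^{-1} q for leading blocks;
    # a zero diagonal marks a null component (response fully deflated) and
    # freezes the path there
    for a in range(1, A + 1):
        if abs(R[a - 1, a - 1]) < 1e-12:
            path[:, a - 1 :] = path[:, a - 2 : a - 1] if a > 1 else 0.0
            break
        alpha = np.linalg.solve(R[:a, :a], q[:a])
        path[:, a - 1] = W[:, :a] @ alpha
    return path


def fit_plsr(X: np.ndarray, y: np.ndarray, ncomp: int, scale: bool = True) -> PLSModel:
    """Fit a PLS1 calibration with ``ncomp`` latent components.

    ``ncomp=0`` is the null model predicting the training mean. Predictors
    and response are centred; with ``scale=True`` they are also divided by
    their sample standard deviations, and the returned coefficients are
    back-transformed to the original measurement scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    if not 0 <= ncomp <= min(n - 1, p):
        raise ValueError(f"ncomp must be in [0, min(n-1, p)] = [0, {min(n - 1, p)}]")
    x_center, x_scale, y_center, y_scale = _center_scale(X, y, scale)
    Xc = (X - x_center) / x_scale
    yc = (y - y_center) / y_scale
    W, P, q, T = _nipals_pls1(Xc, yc, ncomp)
    if ncomp > 0:
        b_scaled = _coef_path(W, P, q)[:, ncomp - 1]
    else:
        b_scaled = np.zeros(p)
    coef = b_scaled * y_scale / x_scale
    intercept = y_center - float(x_center @ coef)
    return PLSModel(
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=intercept,
        ncomp=ncomp,
        scale=scale,
        scores=T,
    )


def predict(model: PLSModel, Xnew: np.ndarray) -> np.ndarray:
    """Apply a calibration: yhat = Xnew @ coef + intercept."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    if Xnew.shape[1] != model.p:
        raise ValueError(
            f"model expects {model.p} predictor columns, got {Xnew.shape[1]}"
        )
    return Xnew @ model.coef + model.intercept


def loo_cv(
    X: np.ndarray, y: np.ndarray, max_ncomp: int = 20, scale: bool = True
) -> CVResult:
    """Leave-one-out cross-validation over component counts 0..max_ncomp.

    Each sample is predicted by a model refitted on the remaining n-1
    (centring and scaling recomputed inside every fold). One NIPALS
    decomposition per fold yields the whole coefficient path, so the cost
    is n fits at max_ncomp rather than n * max_ncomp fits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out CV needs at least 3 samples")
    if not 1 <= max_ncomp <= min(n - 2, p):
        raise ValueError(f"max_ncomp must be in [1, min(n-2, p)] = [1, {min(n - 2, p)}]")
    residuals = np.zeros((n, max_ncomp + 1))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xtr, ytr = X[keep], y[keep]
        x_center, x_scale, y_center, y_scale = _center_scale(Xtr, ytr, scale)
        Xc = (Xtr - x_center) / x_scale
        yc = (ytr - y_center) / y_scale
        W, P, q, _ = _nipals_pls1(Xc, yc, max_ncomp)
        path = _coef_path(W, P, q)  # (p, max_ncomp), centred/scaled scale
        x0 = (X[i] - x_center) / x_scale
        preds = y_center + y_scale * (x0 @ path)
        residuals[i, 0] = y[i] - y_center
        residuals[i, 1:] = y[i] - preds
    sq = residuals**2
    mse = sq.mean(axis=0)
    rmsecv = np.sqrt(mse)
    se_mse = sq.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(rmsecv > 0, se_mse / (2 * rmsecv), 0.0)
    result = CVResult(rmsecv=rmsecv, se=se, chosen_ncomp=0, press_residuals=residuals)
    result.chosen_ncomp = select_ncomp_one_sigma(result)
    return result


def select_ncomp_one_sigma(cv: CVResult) -> int:
    """Fewest components with RMSECV within one standard error of the minimum.

    Ties break toward fewer components; a flat curve selects the
    zero-component (training-mean) model.
    """
    best = int(np.argmin(cv.rmsecv))
    threshold = cv.rmsecv[best] + cv.se[best]
    eligible = np.flatnonzero(cv.rmsecv <= threshold)
    return int(eligible[0])


def get_loadings(model: PLSModel, component: int) -> np.ndarray:
    """x-loading vector (length p) of one component, 1-indexed."""
    if not 1 <= component <= model.ncomp:
        raise ValueError(f"component must be in [1, {model.ncomp}], got {component}")
    return model.x_loadings[:, component - 1].copy()


def save_model(model: PLSModel, path: str | Path, wavelengths: np.ndarray | None = None,
               preprocess: str = "raw") -> Path:
    """Serialize a calibration as flat text: header metadata + per-column rows.

    Rows carry (wavelength, coefficient, x_center, x_scale) at full float
    precision so a reloaded model reproduces predictions bit-exactly.
    """
    path = Path(path)
    p = model.p
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    if wl.size != p:
        raise ValueError(f"wavelengths length {wl.size} != p {p}")
    lines = [
        "# glucospec PLS1 calibration",
        f"ncomp={model.ncomp}",
        f"scale={model.scale}",
        f"y_center={float(model.y_center)!r}",
        f"y_scale={float(model.y_scale)!r}",
        f"intercept={float(model.intercept)!r}",
        f"preprocess={preprocess}",
        "wavelength,coef,x_center,x_scale",
    ]
    for j in range(p):
        lines.append(
            f"{float(wl[j])!r},{float(model.coef[j])!r},"
            f"{float(model.x_center[j])!r},{float(model.x_scale[j])!r}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def load_model(path: str | Path) -> tuple[PLSModel, np.ndarray, str]:
    """Load a calibration saved by :func:`save_model`.

    Returns (model, wavelengths, preprocess label). Weights/loadings are
    not persisted; the reloaded model predicts via (coef, intercept) only.
    """
    lines = Path(path).read_text().strip().splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            continue
        if line == "wavelength,coef,x_center,x_scale":
            body_start = k + 1
            break
        key, _, val = line.partition("=")
        meta[key] = val
    rows = np.array([[float(x) for x in line.split(",")] for line in lines[body_start:]])
    p = rows.shape[0]
    ncomp = int(meta["ncomp"])
    model = PLSModel(
        x_center=rows[:, 2],
        x_scale=rows[:, 3],
        y_center=float(meta["y_center"]),
        y_scale=float(meta["y_scale"]),
        weights=np.zeros((p, ncomp)),
        x_loadings=np.zeros((p, ncomp)),
        y_loadings=np.zeros(ncomp),
        coef=rows[:, 1],
        intercept=float(meta["intercept"]),
        ncomp=ncomp,
        scale=meta["scale"] == "True",
        scores=None,
    )
    return model, rows[:, 0], meta.get("preprocess", "raw")
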