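"""Penalized cubic regression splines for growth trends.

Each muscle's absolute volume (untransformed) and log relative volume
are smoothed against age and against tibia length, separately per sex.
The smoother is a cubic B-spline basis (quantile-placed interior knots)
with a second-order difference penalty on the coefficients:

    minimise ‖W^{1/2}(y − Bβ)‖² + λ‖D₂β‖²

D₂ takes second-order *divided* differences across the Greville
abscissae (the coefficients' natural x-positions), normalized by the
mean abscissa spacing so the penalty is dimensionless: its null space
is exactly the degree-1 polynomials in x even on non-uniform knots, so
λ → ∞ recovers the ordinary least-squares line, and an affine change
of the predictor leaves the penalty — hence the fit at any fixed λ —
unchanged. λ is chosen by generalized
cross-validation (GCV) over a log-spaced grid:

    GCV(λ) = n·RSS(λ) / (n − γ·edf(λ))²,   edf = tr(H(λ)),

with an effective-df inflation γ = 1.4 by default: plain GCV (γ = 1)
is known to undersmooth occasionally, which on a truly flat response
shows up as spurious boundary excursions; mild inflation suppresses
this at negligible cost in fidelity to curved signals.

Under synchronous growth every muscle's relative volume is constant, so
its fitted log-relative-volume curve is flat; the total rise/fall of
each fitted curve against a tolerance is reported as a descriptive
constancy flag (no hypothesis test is attached to the curves — the
inferential claim about synchrony belongs to the isometry test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .cohort import total_volume, volume_col
from .muscles import MUSCLES, SEXES

DEGREE = 3
DEFAULT_BASIS_SIZE = 10
DEFAULT_GRID_POINTS = 200
#: log-units of total rise/fall below which a fitted relative-volume
#: curve is called constant
DEFAULT_FLATNESS_TOL = 0.05
#: effective-df inflation in the GCV score, guarding against GCV's
#: occasional undersmoothing
DEFAULT_GCV_GAMMA = 1.4
_LAMBDA_GRID = np.logspace(-4.0, 8.0, 61)

PREDICTORS = ("age", "tibia_length")


@dataclass
class SplineFit:
    """One penalized cubic spline fit and its evaluation grid."""

    response: str
    predictor: str
    sex: str
    knots: np.ndarray
    coef: np.ndarray
    lam: float
    edf: float
    sigma2: float
    grid: pd.DataFrame           # columns: x, fit, se
    gcv: float
    basis_size: int
    x_data: np.ndarray = None    # observed predictor values (support)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, float), self.knots[DEGREE], self.knots[-DEGREE - 1])
        B = BSpline.design_matrix(x, self.knots, DEGREE).toarray()
        return B @ self.coef

    @property
    def total_change(self) -> float:
        """Rise/fall (max − min) of the curve at the observed predictor
        values — i.e. where the data support it; between data clusters
        (the unscanned 0.3–5 y gap) a spline is unconstrained and its
        excursions say nothing about the cohort."""
        f = self.predict(self.x_data) if self.x_data is not None else self.grid["fit"].to_numpy()
        return float(f.max() - f.min())

    @property
    def trend_sign(self) -> int:
        """+1 if the curve ends higher than it starts, −1 lower, 0 flat."""
        f = self.grid["fit"].to_numpy()
        d = f[-1] - f[0]
        return int(np.sign(d))


def _knot_vector(x: np.ndarray, k_basis: int) -> np.ndarray:
    """Quantile interior knots with (degree+1)-fold boundary knots."""
    xu = np.unique(x)
    lo, hi = float(xu[0]), float(xu[-1])
    n_interior = k_basis - DEGREE - 1
    if n_interior > 0:
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(xu, qs)
        # strictly increasing interior knots inside (lo, hi)
        interior = np.clip(interior, lo + 1e-12 * (hi - lo), hi - 1e-12 * (hi - lo))
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (DEGREE + 1), interior, [hi] * (DEGREE + 1)])


def greville_abscissae(knots: np.ndarray) -> np.ndarray:
    """Greville points ξ_j (running knot averages): the x-position each
    B-spline coefficient is anchored to."""
    k = len(knots) - DEGREE - 1
    return np.array([knots[j + 1 : j + DEGREE + 1].mean() for j in range(k)])


def difference_penalty(knots: np.ndarray) -> np.ndarray:
    """Second-order divided-difference penalty matrix D₂, (K−2) × K.

    Row j applies the second divided difference of the coefficients
    across the Greville abscissae, scaled by the mean abscissa spacing.
    ``D₂β = 0`` iff β is linear in the abscissae, i.e. iff the spline is
    a straight line in x; the scaling makes D₂ invariant to affine
    rescaling of x.
    """
    xi = greville_abscissae(knots)
    k = len(xi)
    h = np.diff(xi)
    if np.any(h <= 0):
        raise ValueError("Greville abscissae must be strictly increasing")
    scale = (xi[-1] - xi[0]) / (k - 1)
    D = np.zeros((k - 2, k))
    for j in range(k - 2):
        D[j, j] = scale / h[j]
        D[j, j + 1] = -scale / h[j] - scale / h[j + 1]
        D[j, j + 2] = scale / h[j + 1]
    return D


def penalized_spline_solve(
    B: np.ndarray,
    y: np.ndarray,
    lam: float,
    D2: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Solve the penalized normal equations for fixed λ.

    Returns (coefficients, edf, rss). Kept separate from the fitting
    front-end so an independent dense ridge solver can be compared
    against it directly.
    """
    n, k = B.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    BtW = B.T * w
    G = BtW @ B + lam * (D2.T @ D2)
    beta = np.linalg.solve(G, BtW @ y)
    # edf = tr(B (BᵀWB + λP)⁻¹ BᵀW) = tr(G⁻¹ BᵀWB)
    edf = float(np.trace(np.linalg.solve(G, BtW @ B)))
    resid = y - B @ beta
    rss = float(np.sum(w * resid * resid))
    return beta, edf, rss


def fit_pspline(
    x: np.ndarray,
    y: np.ndarray,
    k_basis: int = DEFAULT_BASIS_SIZE,
    lam: float | str = "auto",
    weights: np.ndarray | None = None,
    gamma: float = DEFAULT_GCV_GAMMA,
    response: str = "y",
    predictor: str = "x",
    sex: str = "",
    n_grid: int = DEFAULT_GRID_POINTS,
) -> SplineFit:
    """Fit a penalized cubic regression spline.

    Parameters
    ----------
    x, y
        Predictor and response; n ≥ 5 with ≥ 4 distinct predictor
        values. If the distinct values cannot support ``k_basis``
        functions the basis is shrunk with a warning.
    lam
        Fixed smoothing parameter, or ``"auto"`` for GCV selection on a
        log-spaced grid.
    weights
        Optional non-negative case weights (a row with weight w is
        equivalent to w duplicated rows).
    gamma
        Effective-df inflation in the GCV denominator (1 = plain GCV).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if weights is not None:
        weights = np.asarray(weights, float)[ok]
    if len(x) < 5:
        raise ValueError("penalized spline needs n >= 5")
    n_distinct = len(np.unique(x))
    if n_distinct < 4:
        raise ValueError("need at least 4 distinct predictor values")
    k_max = n_distinct + DEGREE - 1
    if k_basis > k_max:
        warnings.warn(
            f"basis size {k_basis} reduced to {k_max} for {n_distinct} distinct x values",
            stacklevel=2,
        )
        k_basis = k_max
    knots = _knot_vector(x, k_basis)
    B = BSpline.design_matrix(x, knots, DEGREE).toarray()
    D2 = difference_penalty(knots)
    n = len(x)

    if lam == "auto":
        best = None
        for lam_try in _LAMBDA_GRID:
            beta, edf, rss = penalized_spline_solve(B, y, lam_try, D2, weights)
            denom = max(n - gamma * edf, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam_try, beta, edf, rss)
        gcv, lam_sel, beta, edf, rss = best
    else:
        lam_sel = float(lam)
        beta, edf, rss = penalized_spline_solve(B, y, lam_sel, D2, weights)
        gcv = n * rss / max(n - gamma * edf, 1e-8) ** 2

    sigma2 = rss / max(n - edf, 1e-8)
    xg = np.linspace(x.min(), x.max(), n_grid)
    Bg = BSpline.design_matrix(xg, knots, DEGREE).toarray()
    # pointwise SE via the sandwich B_g G⁻¹ BᵀWB G⁻¹ B_gᵀ
    w = np.ones(n) if weights is None else weights
    G = (B.T * w) @ B + lam_sel * (D2.T @ D2)
    Ginv_Bg = np.linalg.solve(G, Bg.T)
    cov_core = (B.T * w) @ B
    se = np.sqrt(np.maximum(sigma2 * np.sum(Ginv_Bg * (cov_core @ Ginv_Bg), axis=0), 0.0))
    grid = pd.DataFrame({"x": xg, "fit": Bg @ beta, "se": se})
    return SplineFit(
        response=response, predictor=predictor, sex=sex, knots=knots,
        coef=beta, lam=float(lam_sel), edf=edf, sigma2=float(sigma2),
        grid=grid, gcv=float(gcv), basis_size=k_basis, x_data=x.copy(),
    )


@dataclass
class TrendCollection:
    """Spline fits keyed by (sex, muscle, predictor), plus any failures."""

    fits: dict[tuple[str, str, str], SplineFit] = field(default_factory=dict)
    errors: dict[tuple[str, str, str], str] = field(default_factory=dict)
    flatness_tol: float = DEFAULT_FLATNESS_TOL

    def tidy(self) -> pd.DataFrame:
        """Long-format table of all fitted grids."""
        frames = []
        for (sex, muscle, pred), fit in self.fits.items():
            g = fit.grid.copy()
            g.insert(0, "sex", sex)
            g.insert(1, "muscle", muscle)
            g.insert(2, "predictor", pred)
            frames.append(g)
        if not frames:
            return pd.DataFrame(columns=["sex", "muscle", "predictor", "x", "fit", "se"])
        return pd.concat(frames, ignore_index=True)

    def constancy_flags(self) -> pd.DataFrame:
        """Per fit: total change of the curve and whether it is flat."""
        rows = [
            {
                "sex": sex, "muscle": m, "predictor": p,
                "total_change": fit.total_change,
                "trend_sign": fit.trend_sign,
                "constant": fit.total_change <= self.flatness_tol,
            }
            for (sex, m, p), fit in self.fits.items()
        ]
        return pd.DataFrame(rows)


def _trends(
    cohort: pd.DataFrame,
    response_fn,
    response_name,
    k_basis: int,
    flatness_tol: float,
) -> TrendCollection:
    coll = TrendCollection(flatness_tol=flatness_tol)
    df = cohort[cohort["included"].astype(bool)]
    total = total_volume(df)
    for sex in SEXES:
        sub = df[df["sex"] == sex]
        if len(sub) < 5:
            continue
        tot = total.loc[sub.index]
        for muscle in MUSCLES:
            y = response_fn(sub[volume_col(muscle)].to_numpy(float), tot.to_numpy(float))
            for pred in PREDICTORS:
                key = (sex, muscle, pred)
                try:
                    coll.fits[key] = fit_pspline(
                        sub[pred].to_numpy(float), y, k_basis=k_basis,
                        response=response_name(muscle), predictor=pred, sex=sex,
                    )
                except (ValueError, np.linalg.LinAlgError) as err:
                    coll.errors[key] = str(err)
    return coll


def relative_volume_trends(
    cohort: pd.DataFrame,
    k_basis: int = DEFAULT_BASIS_SIZE,
    flatness_tol: float = DEFAULT_FLATNESS_TOL,
) -> TrendCollection:
    """Log relative volume vs age and tibia length, per sex × muscle.

    Relative volume is V_m / TOTAL; the log transform makes "constant
    proportion" a flat curve and equal relative growth rates equal
    slopes. Per-muscle failures are recorded, not raised.
    """
    return _trends(
        cohort,
        response_fn=lambda v, tot: np.log(v / tot),
        response_name=lambda m: f"log_relvol_{m}",
        k_basis=k_basis,
        flatness_tol=flatness_tol,
    )


def absolute_volume_trends(
    cohort: pd.DataFrame,
    k_basis: int = DEFAULT_BASIS_SIZE,
    flatness_tol: float = DEFAULT_FLATNESS_TOL,
) -> TrendCollection:
    """Absolute volume (cm³, untransformed) vs age and tibia length."""
    return _trends(
        cohort,
        response_fn=lambda v, tot: v,
        response_name=lambda m: f"absvol_{m}",
        k_basis=k_basis,
        flatness_tol=flatness_tol,
    )
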