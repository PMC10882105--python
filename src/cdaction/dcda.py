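"""Dose-space correlated drug action (dCDA) for combination viability matrices.

Each cell in a culture is assumed to carry a latent *lethal dose* for every
drug: treat at or above it and the cell is dead at the assay time.  The
dCDA model predicts the combination viability surface from the two
monotherapy dose-response curves and the Spearman correlation ``rho``
between the two lethal doses across cells.  With Hill-parameterized
monotherapies ``V(D) = 1 / (1 + (D / k)^n)`` and the equivalent-dose maps

    f(DA) = kB * (DA / kA)^(nA / nB)      (dose of B matching A's effect)
    g(DB) = kA * (DB / kB)^(nB / nA)

the model interpolates with weight ``alpha = |rho|``::

    VAB = (1 - alpha) * VA(DA) * VB(DB)
          + alpha * min(VA(DA + g(DB)), VB(DB + f(DA)))     rho >= 0
    VAB = (1 - alpha) * VA(DA) * VB(DB)
          + alpha * max(0, VA(DA) + VB(DB) - 1)             rho <  0

``rho = 0`` is exactly Bliss independence, ``rho = 1`` a sham-compliant
highest-single-agent model (a drug combined with itself obeys
``VAB = VA(DA + DB)``), and ``rho = -1`` the Frechet lower bound.

Fitting mirrors the temporal model: grid search on ``rho`` minimizing RMSE
over the dose matrix, followed by externally-studentized-residual outlier
removal and a refit.  Excess over CDA (EOCDA = predicted - observed) scores
synergy (positive) or antagonism (negative); a leave-one-out z-score test
flags individual dose pairs that deviate from an otherwise well-fitting
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.outliers_influence import OLSInfluence
import statsmodels.api as sm

from .io_formats import DoseMatrix, ValidationError

__all__ = [
    "HillParams",
    "DCDAFit",
    "HillFitError",
    "fit_hill",
    "hill_viability",
    "equivalent_dose",
    "dcda_viability",
    "fit_dcda",
    "flag_outliers",
    "fit_dcda_pipeline",
    "gof_paired_t",
    "eob_validity",
    "eocda",
    "local_dcda_flags",
]

DEFAULT_GRID_SIZE = 200
#: Steepness scan for the Hill exponent: dense enough that the RMSE
#: minimizer is within half a step of the best continuous value.
HILL_N_GRID = np.arange(0.05, 10.0 + 1e-9, 0.01)
#: Number of points in the dense linear interpolation used for the EC50 line fit.
HILL_K_INTERP_POINTS = 200


class HillFitError(ValueError):
    """Monotherapy data cannot be summarized by a decreasing Hill curve."""


@dataclass(frozen=True)
class HillParams:
    """Two-parameter Hill dose-response curve ``V(D) = 1 / (1 + (D/k)^n)``.

    ``k`` is the dose at 50% viability (EC50, drug units) and ``n`` the
    steepness; both must be positive, making V strictly decreasing.
    """

    k: float
    n: float
    drug_label: str = ""

    def __post_init__(self):
        if self.k <= 0 or self.n <= 0:
            raise ValidationError("Hill parameters k and n must be positive")


@dataclass(frozen=True)
class DCDAFit:
    """Result of the full dose-space CDA fitting pipeline on one matrix."""

    rho_hat: float
    rmse: float
    predicted: np.ndarray
    outliers: frozenset
    rho_hat_initial: float
    gof_p: float
    eob_p: float
    eocda: np.ndarray
    local_flags: list | None
    hill_A: HillParams
    hill_B: HillParams
    combination_id: str = ""


def hill_viability(params: HillParams, D) -> float | np.ndarray:
    """Viability of the culture at dose ``D`` under one drug."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be non-negative")
    out = 1.0 / (1.0 + (D / params.k) ** params.n)
    return out if out.ndim else float(out)


def _hill_n_scan(doses: np.ndarray, viab: np.ndarray, k: float) -> float:
    """Steepness minimizing RMSE at the experimental doses for a fixed EC50."""
    with np.errstate(divide="ignore"):
        ratio = doses[None, :] / k
        pred = 1.0 / (1.0 + ratio ** HILL_N_GRID[:, None])
    rmse = np.sqrt(np.mean((pred - viab[None, :]) ** 2, axis=1))
    return float(HILL_N_GRID[np.argmin(rmse)])


def fit_hill(doses, viabilities, drug_label: str = "", refine: bool = True) -> HillParams:
    """Fit a Hill curve to monotherapy viabilities.

    The starting estimate is deliberately simple: viabilities are linearly
    interpolated onto a dense dose grid, rescaled to 0-100, and regressed
    on dose, giving the EC50 as the line's 50% crossing
    ``k = (50 - intercept) / slope``; the steepness ``n`` is then chosen by
    scanning a fixed grid (0.05 to 10, step 0.01) for the RMSE minimizer at
    the experimental doses.  With ``refine=True`` (default) both parameters
    are polished by nonlinear least squares from that starting point —
    downstream correlation estimates are sensitive to EC50 errors of a few
    percent, which the line crossing alone cannot guarantee on sigmoidal
    data.
    """
    doses = np.asarray(doses, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if doses.size != viab.size or doses.size < 3:
        raise ValidationError("need >= 3 paired dose/viability points")
    if np.any(np.diff(doses) <= 0):
        raise ValidationError("doses must be strictly increasing")
    if np.ptp(viab) < 1e-12:
        raise HillFitError("flat viabilities: no dose response to fit")
    dense = np.linspace(doses[0], doses[-1], HILL_K_INTERP_POINTS)
    dense_v = np.interp(dense, doses, viab) * 100.0
    slope, intercept = np.polyfit(dense, dense_v, 1)
    if slope >= 0:
        raise HillFitError(
            f"viability is not decreasing with dose (slope {slope:.3g} >= 0)"
        )
    k = (50.0 - intercept) / slope
    if k <= 0:
        raise HillFitError(f"EC50 estimate {k:.3g} <= 0; curve never crosses 50%")
    n = _hill_n_scan(doses, viab, k)
    if refine:
        try:
            (k_r, n_r), _ = optimize.curve_fit(
                lambda D, k_, n_: 1.0 / (1.0 + (D / k_) ** n_),
                doses,
                viab,
                p0=[k, n],
                bounds=([1e-12, HILL_N_GRID[0]], [np.inf, HILL_N_GRID[-1]]),
                maxfev=10_000,
            )
            k, n = float(k_r), float(n_r)
        except RuntimeError:
            pass  # keep the grid-scan estimate if the polish fails to converge
    return HillParams(k=float(k), n=float(n), drug_label=drug_label)


def equivalent_dose(from_params: HillParams, to_params: HillParams, D):
    """Dose of the target drug producing the same viability as dose ``D``.

    Matched Hill quantiles give ``to_k * (D / from_k)^(from_n / to_n)``;
    by construction ``hill_viability(to, result) == hill_viability(from, D)``.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be non-negative")
    out = to_params.k * (D / from_params.k) ** (from_params.n / to_params.n)
    return out if out.ndim else float(out)


def _branch_surfaces(hill_A: HillParams, hill_B: HillParams, DA, DB):
    """The three rho-independent surfaces the dCDA mixture interpolates.

    Returns (bliss, positive-branch, negative-branch) evaluated on the
    broadcast grid of DA x DB.
    """
    DA = np.asarray(DA, dtype=float)
    DB = np.asarray(DB, dtype=float)
    VA = hill_viability(hill_A, DA)
    VB = hill_viability(hill_B, DB)
    bliss = VA * VB
    enhanced_A = hill_viability(hill_A, DA + equivalent_dose(hill_B, hill_A, DB))
    enhanced_B = hill_viability(hill_B, DB + equivalent_dose(hill_A, hill_B, DA))
    pos = np.minimum(enhanced_A, enhanced_B)
    neg = np.maximum(0.0, VA + VB - 1.0)
    return bliss, pos, neg


def dcda_viability(
    hill_A: HillParams, hill_B: HillParams, DA, DB, rho: float
) -> float | np.ndarray:
    """Predicted combination viability at doses ``(DA, DB)`` and correlation ``rho``."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    bliss, pos, neg = _branch_surfaces(hill_A, hill_B, DA, DB)
    alpha = abs(rho)
    out = (1.0 - alpha) * bliss + alpha * (pos if rho >= 0 else neg)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def _prediction_stack(
    hill_A: HillParams, hill_B: HillParams, doses_A, doses_B, candidates: np.ndarray
) -> np.ndarray:
    """Predicted matrices for every candidate rho, shape (R, |DA|, |DB|)."""
    DA = np.asarray(doses_A, dtype=float)[:, None]
    DB = np.asarray(doses_B, dtype=float)[None, :]
    bliss, pos, neg = _branch_surfaces(hill_A, hill_B, DA, DB)
    alpha = np.abs(candidates)[:, None, None]
    branch = np.where(candidates[:, None, None] >= 0, pos[None], neg[None])
    return (1.0 - alpha) * bliss[None] + alpha * branch


def _fit_hills(matrix: DoseMatrix) -> tuple[HillParams, HillParams]:
    hill_A = fit_hill(matrix.doses_A, matrix.mono_A, drug_label=f"{matrix.combination_id}:A")
    hill_B = fit_hill(matrix.doses_B, matrix.mono_B, drug_label=f"{matrix.combination_id}:B")
    return hill_A, hill_B


def _grid_argmin(candidates: np.ndarray, rmse: np.ndarray) -> int:
    best = rmse.min()
    ties = np.flatnonzero(rmse == best)
    return int(ties[np.lexsort((candidates[ties], np.abs(candidates[ties])))[0]])


def fit_dcda(
    matrix: DoseMatrix,
    grid_size: int = DEFAULT_GRID_SIZE,
    exclude: set | frozenset = frozenset(),
    hills: tuple[HillParams, HillParams] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Grid-search the dCDA correlation on a dose matrix.

    Hill curves are fitted to the monotherapy vectors (or supplied), every
    candidate ``rho`` on a ``grid_size``-point grid over [-1, 1] yields a
    predicted matrix, and the RMSE over non-excluded cells is minimized;
    ties break toward the smallest ``|rho|``.  Returns
    ``(rho_hat, rmse, predicted_matrix)``.
    """
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    hill_A, hill_B = hills if hills is not None else _fit_hills(matrix)
    candidates = np.linspace(-1.0, 1.0, grid_size)
    stack = _prediction_stack(hill_A, hill_B, matrix.doses_A, matrix.doses_B, candidates)
    sq = (stack - matrix.viability[None]) ** 2
    mask = np.ones(matrix.shape, dtype=bool)
    for i, j in exclude:
        mask[i, j] = False
    rmse = np.sqrt(sq[:, mask].mean(axis=1))
    k = _grid_argmin(candidates, rmse)
    return float(candidates[k]), float(rmse[k]), stack[k]


def flag_outliers(observed, predicted) -> frozenset:
    """Outlier cells by externally studentized residuals.

    The observed values are regressed on the predicted ones (intercept and
    slope); residuals studentized with the leave-one-out error estimate
    follow a t distribution with ``n - 3`` degrees of freedom under the
    model, and cells beyond the two-sided Bonferroni cutoff
    ``t_{1 - 0.05 / (2n), n-3}`` are flagged.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    n = observed.size
    if predicted.size != n or n < 5:
        raise ValidationError("need paired vectors of length >= 5")
    if np.ptp(predicted) == 0:
        raise ValidationError("constant predictions: regression is degenerate")
    model = sm.OLS(observed, sm.add_constant(predicted)).fit()
    if np.max(np.abs(model.resid)) <= 1e-12 * max(1.0, float(np.ptp(observed))):
        return frozenset()  # numerically perfect fit: nothing to studentize
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = OLSInfluence(model).resid_studentized_external
    cutoff = stats.t.ppf(1.0 - 0.05 / (2.0 * n), df=n - 3)
    # a perfect fit studentizes to NaN: nothing to flag
    return frozenset(np.flatnonzero(np.abs(resid) > cutoff).tolist())


def gof_paired_t(predicted, observed) -> float:
    """Two-sided paired t-test p-value on (predicted - observed).

    All-zero differences give p = 1; zero-variance non-zero differences are
    degenerate and raise.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.size != observed.size or predicted.size < 3:
        raise ValidationError("need paired vectors of length >= 3")
    diff = predicted - observed
    if np.ptp(diff) <= 1e-12:
        if np.all(np.abs(diff) <= 1e-12):
            return 1.0
        raise ValidationError("constant non-zero differences: t-test undefined")
    return float(stats.ttest_rel(predicted, observed).pvalue)


def eob_validity(matrix: DoseMatrix, hills=None) -> float:
    """p-value for Bliss independence as a null model of this matrix.

    Compares observed viabilities with the ``rho = 0`` dCDA prediction
    (``VA * VB``) by paired t-test.  Excess over Bliss is only a meaningful
    synergy score when this p-value is above the significance threshold.
    """
    hill_A, hill_B = hills if hills is not None else _fit_hills(matrix)
    bliss = dcda_viability(
        hill_A, hill_B, matrix.doses_A[:, None], matrix.doses_B[None, :], 0.0
    )
    return gof_paired_t(bliss, matrix.viability)


def eocda(predicted: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Excess over CDA: predicted minus observed viability, elementwise.

    Positive values mean the culture did worse than correlated independent
    action predicts (likely synergy); negative values suggest antagonism.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValidationError("matrix shapes differ")
    return predicted - observed


@dataclass(frozen=True)
class LocalFlag:
    """Per-dose-pair classification from the leave-one-out local test."""

    index: tuple[int, int]
    p_value: float
    eocda: float
    status: str  # "consistent" | "non_dCDA"
    direction: str | None  # "synergistic" | "antagonistic" | None


def local_dcda_flags(
    matrix: DoseMatrix,
    fit: DCDAFit,
    grid_size: int = DEFAULT_GRID_SIZE,
    alpha: float = 0.01,
) -> list[LocalFlag]:
    """Flag individual dose pairs as locally synergistic or antagonistic.

    Residuals (estimate - observed) over all non-outlier cells are
    summarized by a normal MLE (mu, sigma).  Each cell is then held out,
    ``rho`` refitted without it, the held-out cell re-predicted, and its
    residual converted to the z-score ``(mu - r_i) / sigma`` with a
    two-sided normal p-value.  Cells with ``p <= alpha`` are labeled
    ``non_dCDA``, with the sign of their EOCDA deciding synergistic versus
    antagonistic.  If the residual spread is zero every cell is consistent.
    Meant to be applied only when the global goodness of fit passed.
    """
    candidates = np.linspace(-1.0, 1.0, grid_size)
    stack = _prediction_stack(
        fit.hill_A, fit.hill_B, matrix.doses_A, matrix.doses_B, candidates
    )
    sq = (stack - matrix.viability[None]) ** 2
    mask = np.ones(matrix.shape, dtype=bool)
    for i, j in fit.outliers:
        mask[i, j] = False

    resid_all = fit.predicted[mask] - matrix.viability[mask]
    mu = float(np.mean(resid_all))
    sigma = float(np.std(resid_all))  # MLE: no Bessel correction

    flags = []
    cells = [tuple(ij) for ij in np.argwhere(mask)]
    flat_sq = sq.reshape(sq.shape[0], -1)
    total = flat_sq[:, mask.ravel()].sum(axis=1)
    n_kept = int(mask.sum())
    for i, j in cells:
        if sigma == 0.0:
            flags.append(LocalFlag((i, j), 1.0, 0.0, "consistent", None))
            continue
        loo = total - sq[:, i, j]
        rmse = np.sqrt(loo / (n_kept - 1))
        k = _grid_argmin(candidates, rmse)
        r_i = float(stack[k, i, j] - matrix.viability[i, j])
        z = (mu - r_i) / sigma
        p = float(2.0 * stats.norm.sf(abs(z)))
        if p <= alpha:
            direction = "synergistic" if r_i > 0 else "antagonistic"
            flags.append(LocalFlag((i, j), p, r_i, "non_dCDA", direction))
        else:
            flags.append(LocalFlag((i, j), p, r_i, "consistent", None))
    return flags


def fit_dcda_pipeline(
    matrix: DoseMatrix,
    grid_size: int = DEFAULT_GRID_SIZE,
    local_alpha: float = 0.01,
    gof_alpha: float = 0.01,
) -> DCDAFit:
    """Full dose-space CDA analysis of one combination matrix.

    Initial grid fit, outlier flagging on its predictions, refit excluding
    the flagged cells, then the derived statistics: paired-t goodness of
    fit and Bliss-validity p-values on non-outlier cells, the EOCDA matrix,
    and — when the global fit is adequate (``gof_p > gof_alpha``) — the
    leave-one-out local synergy/antagonism flags.
    """
    hills = _fit_hills(matrix)
    rho0, _, pred0 = fit_dcda(matrix, grid_size, hills=hills)
    flat_outliers = flag_outliers(matrix.viability, pred0)
    shape = matrix.shape
    outliers = frozenset(
        (int(f) // shape[1], int(f) % shape[1]) for f in flat_outliers
    )
    rho1, rmse1, pred1 = fit_dcda(matrix, grid_size, exclude=outliers, hills=hills)

    mask = np.ones(shape, dtype=bool)
    for i, j in outliers:
        mask[i, j] = False
    gof_p = gof_paired_t(pred1[mask], matrix.viability[mask])
    eob_p = eob_validity(matrix, hills=hills)

    fit = DCDAFit(
        rho_hat=rho1,
        rmse=rmse1,
        predicted=pred1,
        outliers=outliers,
        rho_hat_initial=rho0,
        gof_p=gof_p,
        eob_p=eob_p,
        eocda=eocda(pred1, matrix.viability),
        local_flags=None,
        hill_A=hills[0],
        hill_B=hills[1],
        combination_id=matrix.combination_id,
    )
    if gof_p > gof_alpha:
        flags = local_dcda_flags(matrix, fit, grid_size=grid_size, alpha=local_alpha)
        object.__setattr__(fit, "local_flags", flags)
    return fit
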