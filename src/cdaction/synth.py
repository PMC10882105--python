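"""Synthetic cohorts and viability screens with known ground-truth correlation.

Every fitting and testing routine in this package can be exercised without
any external data: this module simulates both study designs under the exact
joint distributions the models assume.

*Lethal doses* for a cell culture are drawn from the mixture in which a
fraction ``|rho|`` of cells lie on the matched-quantile curve
``VA(dA) = VB(dB)`` (anti-matched, ``VA(dA) + VB(dB) = 1``, for negative
``rho``) and the remainder are independent.  The Spearman correlation of
such a mixture equals ``rho`` exactly in expectation.  Marginals are the
Hill-implied lethal-dose distributions, sampled in closed form by inverse
transform: ``delta = k * (u / (1 - u))^(1/n)`` for ``u ~ U(0, 1)``.

*Combination matrices* count surviving cells per dose pair.  In the
correlated component of the mixture a cell survives if its lethal doses
exceed the fully *enhanced* doses ``DA + g(DB)`` and ``DB + f(DA)``; in
the independent component the plain doses apply.  This mirrors how the
closed-form dose-space model weights its branches, so the counting
estimate converges to the model's prediction.  Gaussian measurement noise
is added and clipped to the plate-reader range [0, 1.5].

*Trial sets* build three empirical survival arms from Hill-shaped
monotherapy survival curves, pairing latent times with the coin (or
window-swap) method at the target correlation and taking per-patient
maxima for the combination arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dcda import HillParams, equivalent_dose, hill_viability
from .io_formats import DoseMatrix, TrialSet, ValidationError
from .joint_sim import correlate_pairs_coin, correlate_pairs_window, empirical_survival

__all__ = [
    "SynthSpec",
    "gen_joint_lethal_doses",
    "gen_combination_matrix",
    "gen_trialset",
]


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth description of a synthetic experiment.

    ``hill_A`` / ``hill_B`` parameterize either dose-response curves (for
    matrices) or survival curves over time (for trial sets, with ``k`` in
    months).  ``rho_true`` is the target Spearman correlation of the latent
    pair, ``n_units`` the number of simulated cells or patients, and
    ``noise_sd`` the per-measurement Gaussian noise on viabilities.
    """

    hill_A: HillParams
    hill_B: HillParams
    rho_true: float
    n_units: int = 10_000
    noise_sd: float = 0.0
    n_reps_combo: int = 3
    n_reps_mono: int = 2
    dose_grid_A: np.ndarray | None = None
    dose_grid_B: np.ndarray | None = None
    time_grid: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.rho_true <= 1.0:
            raise ValidationError("rho_true must be in [-1, 1]")
        if self.n_units < 10:
            raise ValidationError("n_units must be >= 10")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_reps_combo < 1 or self.n_reps_mono < 1:
            raise ValidationError("replicate counts must be >= 1")
        for name in ("dose_grid_A", "dose_grid_B", "time_grid"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))


def _hill_inverse_sample(params: HillParams, u: np.ndarray) -> np.ndarray:
    """Closed-form inverse transform of the Hill-implied lethal-dose CDF."""
    return params.k * (u / (1.0 - u)) ** (1.0 / params.n)


def _matched_quantile(params_from: HillParams, params_to: HillParams, delta):
    """delta_B on the rho = 1 curve: V_B(delta_B) = V_A(delta_A)."""
    return equivalent_dose(params_from, params_to, delta)


def _anti_matched(params_from: HillParams, params_to: HillParams, delta):
    """delta_B on the rho = -1 curve: V_B(delta_B) = 1 - V_A(delta_A)."""
    v = hill_viability(params_from, delta)
    u = 1.0 - v  # viability level to invert on the B curve
    return params_to.k * ((1.0 - u) / u) ** (1.0 / params_to.n)


def gen_joint_lethal_doses(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw paired lethal doses from the mixture joint distribution.

    Returns ``(delta_A, delta_B, correlated)`` where ``correlated`` marks
    the cells on the matched (or anti-matched) quantile curve.  The
    Spearman correlation of the pair approaches ``rho_true`` as ``n_units``
    grows.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_units
    u_A = rng.uniform(size=N)
    delta_A = _hill_inverse_sample(spec.hill_A, u_A)
    correlated = rng.uniform(size=N) < abs(spec.rho_true)
    delta_B = _hill_inverse_sample(spec.hill_B, rng.uniform(size=N))
    if spec.rho_true >= 0:
        on_curve = _matched_quantile(spec.hill_A, spec.hill_B, delta_A[correlated])
    else:
        on_curve = _anti_matched(spec.hill_A, spec.hill_B, delta_A[correlated])
    delta_B[correlated] = on_curve
    return delta_A, delta_B, correlated


def _default_dose_grid(params: HillParams, n: int = 10) -> np.ndarray:
    """Log-spaced doses straddling the EC50, spanning ~0.9 to ~0.1 viability."""
    return params.k * np.geomspace(0.25, 4.0, n)


def gen_combination_matrix(spec: SynthSpec) -> DoseMatrix:
    """Simulate a combination viability screen by counting surviving cells.

    For each dose pair, correlated cells survive when both lethal doses
    exceed the enhanced doses ``DA + g(DB)`` / ``DB + f(DA)``; independent
    cells face the plain doses.  Monotherapy vectors come from the marginal
    Hill curves.  ``noise_sd`` is the per-replicate Gaussian measurement
    noise; each reported value averages ``n_reps_combo`` (combination
    wells) or ``n_reps_mono`` (monotherapy wells) replicates, clipped to
    the plate-reader range [0, 1.5].
    """
    rng = np.random.default_rng(spec.seed)
    doses_A = (
        spec.dose_grid_A if spec.dose_grid_A is not None else _default_dose_grid(spec.hill_A)
    )
    doses_B = (
        spec.dose_grid_B if spec.dose_grid_B is not None else _default_dose_grid(spec.hill_B)
    )
    # reuse the seed-derived stream for the pair draw so matrix and pairs agree
    pair_spec = SynthSpec(
        hill_A=spec.hill_A,
        hill_B=spec.hill_B,
        rho_true=spec.rho_true,
        n_units=spec.n_units,
        seed=spec.seed,
    )
    delta_A, delta_B, correlated = gen_joint_lethal_doses(pair_spec)

    DA = doses_A[:, None]
    DB = doses_B[None, :]
    if spec.rho_true >= 0:
        DA_enh = DA + equivalent_dose(spec.hill_B, spec.hill_A, DB)
        DB_enh = DB + equivalent_dose(spec.hill_A, spec.hill_B, DA)
    else:
        DA_enh, DB_enh = np.broadcast_arrays(DA + 0.0 * DB, DB + 0.0 * DA)

    shape = (doses_A.size, doses_B.size)
    viability = np.empty(shape)
    # survival indicators, correlated cells vs enhanced doses
    dA_c, dB_c = delta_A[correlated], delta_B[correlated]
    dA_i, dB_i = delta_A[~correlated], delta_B[~correlated]
    n_c, n_i = dA_c.size, dA_i.size
    surv_c = (
        (dA_c[:, None, None] > DA_enh[None]) & (dB_c[:, None, None] > DB_enh[None])
    ).sum(axis=0)
    surv_i = (
        (dA_i[:, None, None] > (DA + 0.0 * DB)[None])
        & (dB_i[:, None, None] > (DB + 0.0 * DA)[None])
    ).sum(axis=0)
    viability = (surv_c + surv_i) / spec.n_units

    mono_A = hill_viability(spec.hill_A, doses_A)
    mono_B = hill_viability(spec.hill_B, doses_B)
    if spec.noise_sd > 0:
        sd_combo = spec.noise_sd / np.sqrt(spec.n_reps_combo)
        sd_mono = spec.noise_sd / np.sqrt(spec.n_reps_mono)
        viability = viability + rng.normal(scale=sd_combo, size=shape)
        mono_A = mono_A + rng.normal(scale=sd_mono, size=mono_A.shape)
        mono_B = mono_B + rng.normal(scale=sd_mono, size=mono_B.shape)
    viability = np.clip(viability, 0.0, 1.5)
    mono_A = np.clip(mono_A, 0.0, 1.5)
    mono_B = np.clip(mono_B, 0.0, 1.5)

    return DoseMatrix(
        doses_A=doses_A,
        doses_B=doses_B,
        viability=viability,
        mono_A=mono_A,
        mono_B=mono_B,
        treatment_time_h=24.0,
        combination_id=f"synthetic rho={spec.rho_true:g}",
        mono_approximated=False,
    )


def gen_trialset(
    spec: SynthSpec,
    method: Literal["coin", "window_swap"] = "coin",
    tol: float = 0.01,
) -> TrialSet:
    """Simulate a three-arm combination trial at a known correlation.

    Monotherapy survival follows Hill-shaped curves over ``time_grid``
    (default: 0 to 36 months in 0.05-month steps).  ``n_units`` latent time
    pairs are sampled from each curve, paired at ``rho_true`` with the
    chosen method, and the combination arm is the empirical survival of the
    per-patient maxima.  All three arms are returned as empirical curves on
    the same grid so the whole set carries consistent sampling noise.
    """
    rng = np.random.default_rng(spec.seed)
    grid = (
        spec.time_grid
        if spec.time_grid is not None
        else np.arange(0.0, 36.0 + 1e-9, 0.05)
    )
    N = spec.n_units
    # latent times: closed-form Hill inverse, truncated at the grid end
    t_A = np.sort(
        np.minimum(_hill_inverse_sample(spec.hill_A, rng.uniform(size=N)), grid[-1])
    )
    t_B = np.sort(
        np.minimum(_hill_inverse_sample(spec.hill_B, rng.uniform(size=N)), grid[-1])
    )
    if method == "coin":
        pairs = correlate_pairs_coin(t_A, t_B, spec.rho_true, rng)
    elif method == "window_swap":
        pairs = correlate_pairs_window(t_A, t_B, spec.rho_true, tol=tol, seed=rng)
    else:
        raise ValueError(f"unknown pairing method {method!r}")
    t_AB = np.maximum(pairs.t_A, pairs.t_B)
    arm_A = empirical_survival(t_A, grid, n_patients=N, label="drug A (empirical)")
    arm_B = empirical_survival(t_B, grid, n_patients=N, label="drug B (empirical)")
    arm_AB = empirical_survival(
        t_AB, grid, n_patients=N, label=f"combination ({method})"
    )
    return TrialSet(
        arm_A=arm_A,
        arm_B=arm_B,
        arm_AB=arm_AB,
        combination_id=f"synthetic rho={spec.rho_true:g} ({method})",
    )
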