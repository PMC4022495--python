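"""One-set-of-sites isothermal titration calorimetry: forward simulation and
nonlinear least-squares fitting.

Model
-----
n identical independent sites per macromolecule.  With total macromolecule
concentration M_t, total ligand X_t and association constant K_a = 1/K_d,
the bound fraction of sites solves the Wiseman quadratic

    Theta = (1 + X_t/(n M_t) + 1/(n K_a M_t)
             - sqrt((1 + X_t/(n M_t) + 1/(n K_a M_t))^2 - 4 X_t/(n M_t))) / 2

Cell bookkeeping follows the perfusion (fixed effective volume) convention
of MicroCal instruments: after cumulative injected volume dV,

    M_t = M_0 exp(-dV/V0),   X_t = X_syr (1 - exp(-dV/V0)),

and the heat evolved by injection i is

    dQ_i = Q_i - Q_{i-1} + (dv_i/V0) * (Q_i + Q_{i-1})/2 + q_offset

with cell heat content Q_i = n Theta_i M_t,i dH V0, the middle term
accounting for liquid displaced into the inactive tube.

The default bookkeeping is the simpler mole-conserving ("linear") one, in
which the working volume grows with each injection:

    M_t = M_0 V0/(V0+dV),  X_t = X_syr dV/(V0+dV),
    Q_i = n Theta_i M_t,i dH (V0+dV_i),   dQ_i = Q_i - Q_{i-1} + q_offset.

Under it total heat is conserved exactly (cumulative heat equals
n M_0 V0 dH Theta_final plus offsets) and the cumulative molar ratio equals
the injected-moles ratio.  The two conventions differ by a few percent at a
typical 36 uL total into a 280 uL cell; select with ``dilution``.

At the high Wiseman c-values of tight binders (c = n M_0 / K_d >> 1000) the
isotherm is nearly rectangular and K_d is only weakly identified — fits
converge but carry wide confidence intervals, which is exactly the regime
reported for nanomolar amino-acid binding.  K_d is therefore fitted in
log10 space with bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["ItcDesign", "OneSiteParams", "Isotherm", "FitResult",
           "simulate_isotherm", "fit_one_site", "read_heats_tsv", "write_heats_tsv"]


@dataclass
class ItcDesign:
    cell_volume_ml: float = 0.280
    cell_conc_mm: float = 0.05          # macromolecule at start
    syringe_conc_mm: float = 1.25       # ligand
    injection_volumes_ul: list[float] = field(default_factory=lambda: [2.0] * 18)
    temperature_k: float = 298.0

    def __post_init__(self) -> None:
        if min(self.cell_volume_ml, self.cell_conc_mm, self.syringe_conc_mm, self.temperature_k) <= 0:
            raise ValueError("all design quantities must be positive")
        if len(self.injection_volumes_ul) < 2:
            raise ValueError("need at least 2 injections")
        if min(self.injection_volumes_ul) <= 0:
            raise ValueError("injection volumes must be positive")


@dataclass
class OneSiteParams:
    n: float = 1.0              # sites per macromolecule
    k_d: float = 1.3e-9         # molar
    dh: float = -10.0           # kcal/mol
    q_offset: float = 0.0       # ucal per injection (heat of dilution)

    def __post_init__(self) -> None:
        if self.n <= 0 or self.k_d <= 0:
            raise ValueError("n and K_d must be positive")


@dataclass
class Isotherm:
    heats_ucal: np.ndarray          # per injection
    molar_ratio: np.ndarray         # cumulative ligand:macromolecule in the cell

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, float)
        self.molar_ratio = np.asarray(self.molar_ratio, float)
        if self.heats_ucal.shape != self.molar_ratio.shape:
            raise ValueError("heats and molar ratios must have matching length")


@dataclass
class FitResult:
    params: OneSiteParams
    stderr: dict[str, float]
    residuals: np.ndarray
    converged: bool
    no_binding: bool            # flagged when the signal is indistinguishable from zero
    cost: float
    message: str = ""


def _theta(xt: np.ndarray, mt: np.ndarray, n: float, ka: float) -> np.ndarray:
    a = 1.0 + xt / (n * mt) + 1.0 / (n * ka * mt)
    disc = np.maximum(a * a - 4.0 * xt / (n * mt), 0.0)
    return (a - np.sqrt(disc)) / 2.0


def _concentrations(design: ItcDesign, dilution: str) -> tuple[np.ndarray, np.ndarray]:
    """Total cell concentrations (mol/L) of macromolecule and ligand after
    each injection."""
    v0 = design.cell_volume_ml * 1e-3            # L
    dv = np.asarray(design.injection_volumes_ul, float) * 1e-6  # L
    cum = np.cumsum(dv)
    m0 = design.cell_conc_mm * 1e-3              # mol/L
    xs = design.syringe_conc_mm * 1e-3
    if dilution == "exponential":
        mt = m0 * np.exp(-cum / v0)
        xt = xs * (1.0 - np.exp(-cum / v0))
    elif dilution == "linear":
        mt = m0 * v0 / (v0 + cum)
        xt = xs * cum / (v0 + cum)
    else:
        raise ValueError(f"unknown dilution convention {dilution!r}")
    return mt, xt


def _model_heats(design: ItcDesign, n: float, k_d: float, dh: float,
                 q_offset: float, dilution: str) -> np.ndarray:
    v0 = design.cell_volume_ml * 1e-3
    dv = np.asarray(design.injection_volumes_ul, float) * 1e-6
    cum = np.cumsum(dv)
    mt, xt = _concentrations(design, dilution)
    ka = 1.0 / k_d
    theta = _theta(xt, mt, n, ka)
    # heat content in ucal: kcal/mol * mol * 1e9 ucal/kcal
    if dilution == "linear":
        # mole-conserving: heat content tracks total bound moles exactly
        q = n * theta * mt * dh * (v0 + cum) * 1e9
        q_prev = np.concatenate([[0.0], q[:-1]])
        dq = q - q_prev
    else:
        q = n * theta * mt * dh * v0 * 1e9
        q_prev = np.concatenate([[0.0], q[:-1]])
        dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    return dq + q_offset


def simulate_isotherm(
    design: ItcDesign,
    params: OneSiteParams,
    noise_sd_ucal: float = 0.0,
    seed: int = 0,
    dilution: str = "linear",
) -> Isotherm:
    """Forward-simulate per-injection heats; Gaussian noise is deterministic
    per seed."""
    heats = _model_heats(design, params.n, params.k_d, params.dh, params.q_offset, dilution)
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd_ucal, size=len(heats))
    mt, xt = _concentrations(design, dilution)
    return Isotherm(heats_ucal=heats, molar_ratio=xt / mt)


def fit_one_site(
    isotherm: Isotherm,
    design: ItcDesign,
    init: OneSiteParams | None = None,
    dilution: str = "linear",
    log_kd_bounds: tuple[float, float] = (-12.0, -2.0),
) -> FitResult:
    """Nonlinear least squares over (n, log10 K_d, dH, q_offset).

    Standard errors come from the Jacobian at the optimum.  An all-but-flat
    isotherm (total |signal| within the noise of zero) is flagged
    ``no_binding`` — a null titration must not come back as a spuriously
    tight binder.
    """
    y = np.asarray(isotherm.heats_ucal, float)
    if len(y) < 4:
        raise ValueError("need at least 4 injections to fit 4 parameters")
    scale = float(np.max(np.abs(y))) or 1.0

    def resid(p):
        n, logkd, dh, off = p
        return _model_heats(design, n, 10.0 ** logkd, dh, off, dilution) - y

    lo = [1e-3, log_kd_bounds[0], -1e4, -1e6]
    hi = [1e3, log_kd_bounds[1], 1e4, 1e6]
    dh0 = -10.0 if y.sum() < 0 else 10.0
    if init is not None:
        starts = [[init.n, math.log10(init.k_d), init.dh, init.q_offset]]
    else:
        # multistart across the affinity range: the cost surface in log K_d
        # can be multimodal on noisy, nearly rectangular isotherms
        starts = [[1.0, lk, dh0, 0.0] for lk in (-9.0, -7.0, -5.0)]
    sol = None
    for p0 in starts:
        s = least_squares(resid, np.clip(p0, lo, hi), bounds=(lo, hi),
                          xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if sol is None or s.cost < sol.cost:
            sol = s

    n, logkd, dh, off = sol.x
    params = OneSiteParams(n=float(n), k_d=float(10.0 ** logkd), dh=float(dh), q_offset=float(off))

    # asymptotic covariance from J^T J
    stderr = {k: float("nan") for k in ("n", "log10_kd", "dh", "q_offset")}
    dof = max(len(y) - 4, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = np.linalg.inv(JTJ) * s2
        diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = {"n": float(diag[0]), "log10_kd": float(diag[1]),
                  "dh": float(diag[2]), "q_offset": float(diag[3])}
    except np.linalg.LinAlgError:
        pass

    # no-binding detection: the structured (offset-free) part of the fitted
    # model must rise clearly above the residual noise floor
    model_shape = _model_heats(design, params.n, params.k_d, params.dh, 0.0, dilution)
    amplitude = float(np.max(np.abs(model_shape)))
    resid_sd = float(np.sqrt(np.mean(sol.fun ** 2)))
    flat_data = float(np.sqrt(np.mean((y - np.median(y)) ** 2))) < 1e-9 * scale
    no_binding = flat_data or amplitude < 3.0 * resid_sd or abs(params.dh) < 1e-3
    return FitResult(
        params=params,
        stderr=stderr,
        residuals=sol.fun,
        converged=bool(sol.success),
        no_binding=bool(no_binding),
        cost=float(sol.cost),
        message=str(sol.message),
    )


def read_heats_tsv(path) -> np.ndarray:
    """Two-column TSV (injection index, heat in ucal) -> heats array."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["injection", "heat_ucal"])
    return df["heat_ucal"].to_numpy(float)


def write_heats_tsv(path, heats: np.ndarray) -> None:
    import pandas as pd

    pd.DataFrame({"injection": np.arange(1, len(heats) + 1), "heat_ucal": heats}) \
        .to_csv(path, sep="\t", index=False, header=False)
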