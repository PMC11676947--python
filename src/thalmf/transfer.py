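"""Semi-analytic transfer function for conductance-based AdEx cells.

The chain is: presynaptic rates (nu_e, nu_i) -> shotnoise conductance moments
-> subthreshold membrane moments (muV, sigmaV, tauV) -> an effective spike
threshold given by a second-order polynomial in the normalized moments -> the
output rate

    nu_out = 1/(2 tauV) * erfc((V_thr_eff - muV) / (sqrt(2) sigmaV)).

The ten polynomial amplitudes {P} are cell-type specific and obtained by a
two-stage fit to single-cell simulations: a linear fit in threshold space
(inverting the erfc) provides the initial guess for a nonlinear least-squares
fit in rate space.  One fit per cell type is shared across awake/sleep states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc, erfcinv

from .cell import run_poisson_batch
from .params import CellParams, tf_normalization, reference_coefficients

__all__ = [
    "InputConnectivity",
    "FluctuationMoments",
    "TFCoefficients",
    "conductance_moments",
    "membrane_moments",
    "effective_threshold",
    "transfer_rate",
    "stationary_adaptation",
    "default_rate_grid",
    "sample_single_cell_rates",
    "TransferFunctionModel",
    "TransferFunctionResults",
    "fit_transfer_function",
]

logger = logging.getLogger(__name__)

COEFF_NAMES = ("P0", "Pmu", "Psig", "Ptau", "Pmumu", "Pmusig",
               "Pmutau", "Psigsig", "Psigtau", "Ptautau")


@dataclass(frozen=True)
class InputConnectivity:
    """Mean synaptic in-degrees K = p*N plus the target cell's parameters."""

    K_e: float
    K_i: float
    params: CellParams

    def __post_init__(self) -> None:
        if self.K_e < 0 or self.K_i < 0:
            raise ValueError("in-degrees must be non-negative")


@dataclass
class FluctuationMoments:
    """Subthreshold membrane statistics under Poisson bombardment."""

    muV: np.ndarray        # mV
    sigmaV: np.ndarray     # mV
    tauV: np.ndarray       # ms
    tauVN: np.ndarray      # dimensionless tauV * gL / cm
    muG: np.ndarray        # nS, total input conductance
    tau_m: np.ndarray      # ms, effective membrane time cm/muG


@dataclass(frozen=True)
class TFCoefficients:
    """Effective-threshold polynomial amplitudes (mV) + normalization."""

    P: np.ndarray                      # shape (10,), order COEFF_NAMES
    norm: dict = field(default_factory=tf_normalization)
    cell: str = ""

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (10,):
            raise ValueError("need exactly 10 polynomial amplitudes")
        if not np.all(np.isfinite(P)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "P", P)

    @classmethod
    def reference(cls, cell: str) -> "TFCoefficients":
        """The shipped reference amplitudes for 'TC' or 'RE'."""
        return cls(P=np.asarray(reference_coefficients(cell)), cell=cell)

    def to_series(self) -> pd.Series:
        return pd.Series(self.P, index=list(COEFF_NAMES), name=self.cell or "P")


def conductance_moments(nu_e, nu_i, ic: InputConnectivity,
                        Qe: float | None = None, Qi: float | None = None):
    """Shotnoise conductance moments (muGe, muGi, sigmaGe, sigmaGi, muG) in nS.

    mu_G = nu K tau Q and sigma_G = Q sqrt(nu K tau / 2), with tau in seconds
    so the nu*tau product is dimensionless.
    """
    nu_e = np.asarray(nu_e, dtype=float)
    nu_i = np.asarray(nu_i, dtype=float)
    if np.any(nu_e < 0) or np.any(nu_i < 0):
        raise ValueError("rates must be non-negative")
    p = ic.params
    qe = p.Qe if Qe is None else Qe
    qi = p.Qi if Qi is None else Qi
    te, ti = p.tau_e * 1e-3, p.tau_i * 1e-3
    muGe = nu_e * ic.K_e * te * qe
    muGi = nu_i * ic.K_i * ti * qi
    sGe = qe * np.sqrt(nu_e * ic.K_e * te / 2.0)
    sGi = qi * np.sqrt(nu_i * ic.K_i * ti / 2.0)
    muG = muGe + muGi + p.gL
    return muGe, muGi, sGe, sGi, muG


def membrane_moments(
    nu_e, nu_i, w, ic: InputConnectivity,
    Qe: float | None = None,
    extra_exc: list[tuple] | None = None,
    static_ge: float | np.ndarray = 0.0,
    static_gi: float | np.ndarray = 0.0,
) -> FluctuationMoments:
    """Membrane moments (muV, sigmaV, tauV) from input rates and adaptation.

    ``extra_exc`` lists additional excitatory spiking channels as tuples
    (rate_Hz, K, Q) sharing tau_e and Ee (used for common-drive protocols).
    ``static_ge``/``static_gi`` are non-fluctuating extra conductances (nS)
    with the synaptic reversal potentials; they shift muV and the effective
    membrane time constant but contribute no shotnoise of their own.
    """
    p = ic.params
    nu_e = np.asarray(nu_e, dtype=float)
    nu_i = np.asarray(nu_i, dtype=float)
    w = np.asarray(w, dtype=float)
    muGe, muGi, _, _, _ = conductance_moments(nu_e, nu_i, ic, Qe=Qe)
    qe = p.Qe if Qe is None else Qe

    # spiking channels: (K, nu, Q, tau_s, E)
    channels = [
        (ic.K_e, nu_e, qe, p.tau_e * 1e-3, p.Ee),
        (ic.K_i, nu_i, p.Qi, p.tau_i * 1e-3, p.Ei),
    ]
    numer_extra = 0.0
    muG_extra = 0.0
    if extra_exc:
        for rate, K, Q in extra_exc:
            mg = np.asarray(rate, dtype=float) * K * (p.tau_e * 1e-3) * Q
            numer_extra = numer_extra + mg * p.Ee
            muG_extra = muG_extra + mg
            channels.append((K, np.asarray(rate, dtype=float), Q, p.tau_e * 1e-3, p.Ee))

    static_ge = np.asarray(static_ge, dtype=float)
    static_gi = np.asarray(static_gi, dtype=float)
    muG = muGe + muGi + p.gL + muG_extra + static_ge + static_gi
    muV = (
        muGe * p.Ee + muGi * p.Ei + p.gL * p.EL - w
        + numer_extra + static_ge * p.Ee + static_gi * p.Ei
    ) / muG
    tau_m = p.cm / muG                      # ms
    tm_s = tau_m * 1e-3

    var = 0.0
    num_tau = 0.0
    den_tau = 0.0
    for K, nu, Q, tau_s, E in channels:
        U = (Q / muG) * (E - muV)           # mV, effective synaptic drive
        contrib = K * nu * (U * tau_s) ** 2
        var = var + contrib / (2.0 * (tm_s + tau_s))
        num_tau = num_tau + contrib
        den_tau = den_tau + contrib / (tm_s + tau_s)

    sigmaV = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        tauV_s = np.where(den_tau > 0, num_tau / np.where(den_tau > 0, den_tau, 1.0),
                          tm_s + max(p.tau_e, p.tau_i) * 1e-3)
    tauV = tauV_s * 1e3
    tauVN = tauV * p.gL / p.cm
    return FluctuationMoments(muV=muV, sigmaV=sigmaV, tauV=tauV, tauVN=tauVN,
                              muG=muG, tau_m=tau_m)


def _features(muV, sigmaV, tauVN, norm: dict) -> np.ndarray:
    """Normalized polynomial feature matrix, one row per input, 10 columns.

    The normalization delimits the fluctuation-driven regime the polynomial
    is fitted on; outside it a second-order polynomial extrapolates without
    control (the effective threshold can outrun muV, capping the rate where
    it should saturate), so the features are frozen at the regime edge
    (``norm['clip']`` normalized units, default 2).  Beyond the edge the
    erfc itself provides the physical saturation.
    """
    clip = norm.get("clip", 3.0)
    xm = (np.asarray(muV) - norm["muV0"]) / norm["dmuV0"]
    xs = (np.asarray(sigmaV) - norm["sigmaV0"]) / norm["dsigmaV0"]
    xt = (np.asarray(tauVN) - norm["tauVN0"]) / norm["dtauVN0"]
    # smooth (tanh) saturation keeps the polynomial's derivatives continuous,
    # which the mean-field's finite-difference Hessian relies on
    xm = clip * np.tanh(xm / clip)
    xs = clip * np.tanh(xs / clip)
    xt = clip * np.tanh(xt / clip)
    ones = np.ones_like(xm)
    return np.stack(
        [ones, xm, xs, xt, xm * xm, xm * xs, xm * xt, xs * xs, xs * xt, xt * xt],
        axis=-1,
    )


def effective_threshold(m: FluctuationMoments, coeffs: TFCoefficients):
    """Effective spike threshold V_thr_eff (mV), polynomial in the moments."""
    X = _features(m.muV, m.sigmaV, m.tauVN, coeffs.norm)
    return X @ coeffs.P


def transfer_rate(
    nu_e, nu_i, w, coeffs: TFCoefficients, ic: InputConnectivity,
    Qe: float | None = None,
    extra_exc: list[tuple] | None = None,
    static_ge=0.0, static_gi=0.0,
):
    """Output rate nu_out (Hz) = 1/(2 tauV) erfc((Vthr_eff - muV)/(sqrt2 sigmaV)).

    In the degenerate sigmaV = 0 limit the rate is the step function: 0 below
    threshold, 1/tauV above.
    """
    m = membrane_moments(nu_e, nu_i, w, ic, Qe=Qe, extra_exc=extra_exc,
                         static_ge=static_ge, static_gi=static_gi)
    vthr = effective_threshold(m, coeffs)
    tauV_s = m.tauV * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (vthr - m.muV) / (np.sqrt(2.0) * m.sigmaV)
        rate = erfc(arg) / (2.0 * tauV_s)
    step = np.where(np.asarray(m.muV) > vthr, 1.0 / tauV_s, 0.0)
    rate = np.where(np.asarray(m.sigmaV) > 0, rate, step)
    return rate if np.ndim(rate) else float(rate)


def stationary_adaptation(
    nu_out, nu_e, nu_i, ic: InputConnectivity,
    tol: float = 0.01, max_iter: int = 100, damping: float = 0.5,
    Qe: float | None = None,
):
    """Self-consistent stationary adaptation w* (pA) given a measured rate.

    Solves w = tau_w * b * nu_out + a * (muV(nu_e, nu_i, w) - EL) by damped
    fixed-point iteration (tau_w in seconds so b*nu_out is in pA).
    """
    p = ic.params
    nu_out = np.asarray(nu_out, dtype=float)
    w = np.zeros(np.broadcast(nu_out, np.asarray(nu_e)).shape, dtype=float)
    base = p.tau_w * 1e-3 * p.b * nu_out
    for _ in range(max_iter):
        muV = membrane_moments(nu_e, nu_i, w, ic, Qe=Qe).muV
        w_new = base + p.a * (muV - p.EL)
        delta = np.max(np.abs(w_new - w)) if np.ndim(w_new) else abs(w_new - w)
        w = (1 - damping) * w + damping * w_new
        if delta < tol:
            break
    else:
        logger.warning("stationary adaptation iteration did not reach %g pA", tol)
    return w if np.ndim(w) else float(w)


def default_rate_grid(n_e: int = 16, nu_i_values=(0.0, 5.0, 10.0, 20.0, 40.0)):
    """(nu_e, nu_i) sample grid: log-spaced nu_e in [2, 400] Hz x nu_i set.

    The nu_e range brackets the firing onset at every nu_i level so that
    roughly half the grid lies in the fluctuation-driven active regime the
    polynomial threshold has to capture.
    """
    nu_e = np.geomspace(2.0, 400.0, n_e)
    grid = [(ne, ni) for ni in nu_i_values for ne in nu_e]
    return grid


def sample_single_cell_rates(
    params: CellParams,
    ic: InputConnectivity,
    grid,
    duration: float = 5000.0,
    reps: int = 100,
    seed=None,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Monte-Carlo single-cell rate table over a (nu_e, nu_i) grid.

    Each grid point drives one cell with K_e*nu_e excitatory and K_i*nu_i
    inhibitory Poisson input for ``duration`` ms, averaged over ``reps``
    independent runs.  Returns columns nu_e, nu_i, rate, sd, sem, reps.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    nu_e_tot = np.repeat([ne * ic.K_e for ne, _ in grid], reps)
    nu_i_tot = np.repeat([ni * ic.K_i for _, ni in grid], reps)
    res = run_poisson_batch(params, nu_e_tot, nu_i_tot, duration, dt=dt, seed=seed)
    rates = res["counts"].reshape(len(grid), reps) / (duration * 1e-3)
    sd = rates.std(axis=1, ddof=1) if reps > 1 else np.zeros(len(grid))
    return pd.DataFrame({
        "nu_e": [ne for ne, _ in grid],
        "nu_i": [ni for _, ni in grid],
        "rate": rates.mean(axis=1),
        "sd": sd,
        "sem": sd / np.sqrt(reps),
        "reps": reps,
    })


class TransferFunctionModel:
    """Two-stage fit of the effective-threshold amplitudes to rate data.

    Parameters
    ----------
    rate_table : DataFrame with columns nu_e, nu_i, rate (Hz) and optionally
        sd / sem (Monte-Carlo uncertainty per point).
    params : the cell's AdEx parameters (adaptation enters through the
        stationary solution of the population adaptation equation).
    ic : input connectivity used when the table was sampled.
    """

    def __init__(self, rate_table: pd.DataFrame, params: CellParams,
                 ic: InputConnectivity, norm: dict | None = None):
        required = {"nu_e", "nu_i", "rate"}
        if not required.issubset(rate_table.columns):
            raise ValueError(f"rate table needs columns {sorted(required)}")
        self.table = rate_table.reset_index(drop=True)
        self.params = params
        self.ic = ic
        self.norm = dict(norm) if norm is not None else tf_normalization()
        self._prepare()

    def _prepare(self) -> None:
        t = self.table
        self._w = stationary_adaptation(
            t["rate"].to_numpy(), t["nu_e"].to_numpy(), t["nu_i"].to_numpy(), self.ic
        )
        self._m = membrane_moments(
            t["nu_e"].to_numpy(), t["nu_i"].to_numpy(), self._w, self.ic
        )

    def _stage1(self):
        t = self.table
        rate = t["rate"].to_numpy()
        tauV_s = self._m.tauV * 1e-3
        # invertible only strictly inside the erfc range
        ok = (rate > 0) & (rate < 1.0 / tauV_s) & (self._m.sigmaV > 0)
        n_excluded = int((~ok).sum())
        if n_excluded:
            logger.info("stage 1: excluding %d points outside the invertible range",
                        n_excluded)
        if ok.sum() < 10:
            raise ValueError(
                f"only {int(ok.sum())} invertible points; need at least 10 for the "
                "10-amplitude linear fit"
            )
        vthr = (self._m.muV[ok]
                + np.sqrt(2.0) * self._m.sigmaV[ok]
                * erfcinv(2.0 * tauV_s[ok] * rate[ok]))
        X = _features(self._m.muV[ok], self._m.sigmaV[ok], self._m.tauVN[ok], self.norm)
        P0, *_ = np.linalg.lstsq(X, vthr, rcond=None)
        return P0, n_excluded

    def fit(self, weighted: bool = False, max_nfev: int = 2000,
            min_active: int = 30) -> "TransferFunctionResults":
        """Stage-1 linear threshold-space fit, then nonlinear rate-space fit.

        Requires at least ``min_active`` grid points with nonzero output rate
        (default 30) so the 10-amplitude polynomial is well constrained.
        """
        t = self.table
        rate = t["rate"].to_numpy()
        n_active = int((rate > 0).sum())
        if n_active < min_active:
            raise ValueError(
                f"rate table has only {n_active} active points; "
                f"need >= {min_active} in the fluctuation-driven regime")
        nu_e = t["nu_e"].to_numpy()
        nu_i = t["nu_i"].to_numpy()
        P_init, n_excluded = self._stage1()
        weights = np.ones_like(rate)
        if weighted:
            sem = t["sem"].to_numpy() if "sem" in t else t.get("sd", pd.Series(np.ones_like(rate))).to_numpy()
            weights = 1.0 / np.clip(sem, np.percentile(sem[sem > 0], 10) if (sem > 0).any() else 1.0, None)

        w_stat = self._w

        def residuals(P):
            coeffs = TFCoefficients(P=P, norm=self.norm)
            pred = transfer_rate(nu_e, nu_i, w_stat, coeffs, self.ic)
            return (np.asarray(pred) - rate) * weights

        sol = least_squares(residuals, P_init, max_nfev=max_nfev, method="lm")
        if not sol.success:
            raise RuntimeError(
                f"nonlinear stage did not converge: {sol.message}; "
                f"final residual norm {np.linalg.norm(sol.fun):.3g}"
            )
        coeffs = TFCoefficients(P=sol.x, norm=self.norm, cell=self.params.label)
        pred = transfer_rate(nu_e, nu_i, w_stat, coeffs, self.ic)
        rmse = float(np.sqrt(np.mean((np.asarray(pred) - rate) ** 2)))
        return TransferFunctionResults(
            model=self, coeffs=coeffs, stage1_P=np.asarray(P_init),
            rmse=rmse, n_points=len(rate), n_excluded=n_excluded,
        )


@dataclass
class TransferFunctionResults:
    """Fitted amplitudes plus diagnostics; supports predict() and summary()."""

    model: TransferFunctionModel
    coeffs: TFCoefficients
    stage1_P: np.ndarray
    rmse: float              # Hz, rate-space
    n_points: int
    n_excluded: int

    def predict(self, nu_e, nu_i, w=None):
        """Predicted output rate; w defaults to the stationary adaptation."""
        if w is None:
            # self-consistent: iterate rate <-> stationary adaptation
            rate = np.zeros(np.broadcast(np.asarray(nu_e), np.asarray(nu_i)).shape)
            for _ in range(50):
                w_stat = stationary_adaptation(rate, nu_e, nu_i, self.model.ic)
                new = transfer_rate(nu_e, nu_i, w_stat, self.coeffs, self.model.ic)
                if np.max(np.abs(np.asarray(new) - rate)) < 1e-3:
                    rate = np.asarray(new)
                    break
                rate = 0.5 * rate + 0.5 * np.asarray(new)
            return rate
        return transfer_rate(nu_e, nu_i, w, self.coeffs, self.model.ic)

    def summary(self) -> str:
        lines = [
            "Transfer function fit",
            "=" * 44,
            f"cell: {self.model.params.label or '<unnamed>'}",
            f"points: {self.n_points} (stage-1 excluded: {self.n_excluded})",
            f"rate-space RMSE: {self.rmse:.3f} Hz",
            "-" * 44,
            f"{'coef':>8} {'stage1 (mV)':>12} {'final (mV)':>12}",
        ]
        for name, p1, p2 in zip(COEFF_NAMES, self.stage1_P, self.coeffs.P):
            lines.append(f"{name:>8} {p1:12.3f} {p2:12.3f}")
        return "\n".join(lines)


def fit_transfer_function(rate_table: pd.DataFrame, params: CellParams,
                          ic: InputConnectivity, **fit_kw) -> TransferFunctionResults:
    """Convenience wrapper: build the model and run the two-stage fit."""
    return TransferFunctionModel(rate_table, params, ic).fit(**fit_kw)
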