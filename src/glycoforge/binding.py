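"""Antibody-binding analytics: SPR 1:1 Langmuir kinetics and 4PL ELISA.

SPR
    The 1:1 Langmuir model for a sensorgram with analyte concentration
    C, association phase of length t_a and dissociation afterwards:

        association:  R(t) = Req * (1 - exp(-(ka*C + kd) * t)),
                      Req  = Rmax * C / (C + KD),  KD = kd / ka
        dissociation: R(t) = R(t_a) * exp(-kd * (t - t_a))

    ka is the association rate constant in 1/(M s), kd the dissociation
    rate constant in 1/s.  KD is carried internally in molar and
    reported in nM (the convention of SPR kinetic tables).
    :func:`fit_langmuir` fits (ka, kd, Rmax) globally across sensorgrams
    at several concentrations by least squares in log-parameter space.

ELISA
    Dose-response curves are fit with the four-parameter logistic

        y(x) = bottom + (top - bottom) / (1 + (EC50 / x)^hill)

    parameterized so hill > 0 gives an increasing curve, matching ELISA
    signal direction; EC50 is the concentration at half-maximal signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConvergenceError, FitQualityError, ValidationError

LN10 = float(np.log(10.0))


class IdentifiabilityWarning(UserWarning):
    """Experimental design too thin to pin down all kinetic parameters."""


# --------------------------------------------------------------------------
# SPR rate constants and the derived dissociation constant
# --------------------------------------------------------------------------

def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd/ka, reported in nM."""
    if ka <= 0:
        raise ValidationError(f"association rate ka must be > 0, got {ka}")
    if kd < 0:
        raise ValidationError(f"dissociation rate kd must be >= 0, got {kd}")
    return (kd / ka) * 1e9


@dataclass(frozen=True)
class SPRRecord:
    """One analyte's 1:1 kinetic constants from an SPR experiment."""

    analyte: str
    ka: float  # 1/(M s)
    kd: float  # 1/s
    antibody: str = ""

    def __post_init__(self):
        kd_from_rates(self.ka, self.kd)  # validates signs

    @property
    def KD_nM(self) -> float:
        return kd_from_rates(self.ka, self.kd)


# --------------------------------------------------------------------------
# Sensorgram model, simulation, global fitting
# --------------------------------------------------------------------------

@dataclass
class Sensorgram:
    """A response-vs-time trace at one analyte concentration."""

    time: np.ndarray            # s
    response: np.ndarray        # RU
    concentration: float        # M
    t_assoc: float              # s, end of association phase
    rmax: float | None = None   # RU, if known (simulated data)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValidationError("time and response grids differ in length")
        if self.concentration < 0:
            raise ValidationError("analyte concentration must be >= 0")
        if self.t_assoc <= 0:
            raise ValidationError("association time must be > 0")


def langmuir_response(
    t: np.ndarray, ka: float, kd: float, concentration: float,
    rmax: float, t_assoc: float,
) -> np.ndarray:
    """Noiseless 1:1 Langmuir response over a time grid spanning both phases."""
    t = np.asarray(t, dtype=float)
    kobs = ka * concentration + kd
    with np.errstate(divide="ignore", invalid="ignore"):
        req = rmax * concentration / (concentration + kd / ka)
    assoc = req * (1.0 - np.exp(-kobs * np.clip(t, 0.0, None)))
    r_at_ta = req * (1.0 - np.exp(-kobs * t_assoc))
    # clip keeps the discarded where-branch from overflowing for t << t_a
    dissoc = r_at_ta * np.exp(-kd * np.clip(t - t_assoc, 0.0, None))
    return np.where(t <= t_assoc, assoc, dissoc)


def simulate_sensorgram(
    ka: float, kd: float, concentration: float, rmax: float,
    t_assoc: float = 120.0, t_total: float = 320.0,
    noise_sd: float = 0.0, seed: int | None = None, dt: float = 1.0,
) -> Sensorgram:
    """Simulate a sensorgram; Gaussian noise requires an explicit seed.

    Defaults mirror a standard kinetic run: 120 s association followed
    by 200 s dissociation, sampled at 1 Hz.
    """
    if ka <= 0 or kd < 0 or rmax <= 0:
        raise ValidationError("ka, rmax must be > 0 and kd >= 0")
    if concentration < 0:
        raise ValidationError("analyte concentration must be >= 0")
    if not 0 < t_assoc < t_total:
        raise ValidationError("need 0 < t_assoc < t_total")
    t = np.arange(0.0, t_total + dt / 2, dt)
    r = langmuir_response(t, ka, kd, concentration, rmax, t_assoc)
    if noise_sd > 0:
        if seed is None:
            raise ValidationError("noisy simulation requires an explicit seed")
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(
        time=t, response=r, concentration=concentration,
        t_assoc=t_assoc, rmax=rmax,
    )


@dataclass(frozen=True)
class LangmuirFit:
    """Global 1:1 fit result across sensorgrams."""

    ka: float
    kd: float
    rmax: float
    se_ka: float
    se_kd: float
    se_rmax: float
    rmse: float
    n_points: int
    n_curves: int

    @property
    def KD_nM(self) -> float:
        return kd_from_rates(self.ka, self.kd)

    def to_dict(self) -> dict:
        return {
            "ka_per_M_s": self.ka, "kd_per_s": self.kd, "rmax_RU": self.rmax,
            "KD_nM": self.KD_nM, "se_ka": self.se_ka, "se_kd": self.se_kd,
            "se_rmax": self.se_rmax, "rmse_RU": self.rmse,
            "n_points": self.n_points, "n_curves": self.n_curves,
        }


def _tail_kd_guess(sg: Sensorgram) -> float:
    """Crude kd from the log-linear dissociation tail of one curve."""
    mask = sg.time > sg.t_assoc
    t, r = sg.time[mask], sg.response[mask]
    pos = r > max(1e-3, 0.02 * np.max(np.abs(sg.response)))
    if pos.sum() < 4:
        return 1e-2
    slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
    return float(np.clip(-slope, 1e-6, 10.0))


def fit_langmuir(
    sensorgrams: list[Sensorgram],
    starts_ka: tuple[float, ...] = (1e3, 1e4, 1e5, 1e6),
) -> LangmuirFit:
    """Global least-squares fit of shared (ka, kd, Rmax) to >= 1 sensorgrams.

    Parameters are optimized in log10 space (enforcing positivity); the
    fit is restarted from a small deterministic grid of ka guesses and
    the lowest-cost solution is kept.  Standard errors are asymptotic,
    from the Jacobian at the optimum.  Designs with fewer than three
    distinct concentrations trigger an :class:`IdentifiabilityWarning`
    (ka and Rmax are then nearly confounded).
    """
    if not sensorgrams:
        raise ValidationError("need at least one sensorgram")
    n_conc = len({sg.concentration for sg in sensorgrams})
    if n_conc < 3:
        warnings.warn(
            f"only {n_conc} distinct analyte concentration(s): ka and Rmax "
            "are weakly identified; use >= 3 concentrations spanning "
            "0.1-10 x KD",
            IdentifiabilityWarning,
            stacklevel=2,
        )

    obs = np.concatenate([sg.response for sg in sensorgrams])
    rmax0 = 1.05 * float(np.max(obs))
    kd0 = _tail_kd_guess(max(sensorgrams, key=lambda s: s.concentration))

    def residuals(theta: np.ndarray) -> np.ndarray:
        ka, kd, rmax = 10.0 ** theta
        parts = [
            langmuir_response(sg.time, ka, kd, sg.concentration, rmax, sg.t_assoc)
            - sg.response
            for sg in sensorgrams
        ]
        return np.concatenate(parts)

    best = None
    for ka0 in starts_ka:
        theta0 = np.log10([ka0, kd0, rmax0])
        try:
            res = optimize.least_squares(
                residuals, theta0, method="lm",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise ConvergenceError(
            "1:1 Langmuir fit did not converge from any starting point",
            diagnostics={"starts_ka": starts_ka, "kd0": kd0, "rmax0": rmax0},
        )

    theta = best.x
    ka, kd, rmax = (float(v) for v in 10.0 ** theta)
    m, p = len(obs), 3
    dof = max(m - p, 1)
    s2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov_log = s2 * np.linalg.inv(jtj)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    except np.linalg.LinAlgError:
        se_log = np.full(3, np.nan)
    se = LN10 * np.array([ka, kd, rmax]) * se_log  # delta method
    return LangmuirFit(
        ka=ka, kd=kd, rmax=rmax,
        se_ka=float(se[0]), se_kd=float(se[1]), se_rmax=float(se[2]),
        rmse=float(np.sqrt(2.0 * best.cost / m)),
        n_points=m, n_curves=len(sensorgrams),
    )


# --------------------------------------------------------------------------
# ELISA: 4-parameter logistic dose-response
# --------------------------------------------------------------------------

@dataclass
class ELISACurve:
    """Concentration (ng/ml) vs optical-density points for one analyte."""

    concentration: np.ndarray
    response: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.shape != self.response.shape:
            raise ValidationError("concentration and response differ in length")
        if np.any(self.concentration <= 0):
            raise ValidationError("concentrations must be > 0 for a 4PL fit")


def four_pl(x, bottom: float, top: float, ec50: float, hill: float):
    """The 4-parameter logistic, increasing for hill > 0."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    se_bottom: float
    se_top: float
    se_ec50: float
    se_hill: float
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "bottom": self.bottom, "top": self.top, "ec50": self.ec50,
            "hill": self.hill, "se_bottom": self.se_bottom,
            "se_top": self.se_top, "se_ec50": self.se_ec50,
            "se_hill": self.se_hill, "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def simulate_elisa_curve(
    concentrations, bottom: float, top: float, ec50: float, hill: float,
    noise_sd: float = 0.0, seed: int | None = None, label: str = "",
) -> ELISACurve:
    """Synthetic dose-response points from known 4PL parameters."""
    x = np.asarray(concentrations, dtype=float)
    y = four_pl(x, bottom, top, ec50, hill)
    if noise_sd > 0:
        if seed is None:
            raise ValidationError("noisy simulation requires an explicit seed")
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return ELISACurve(concentration=x, response=y, label=label)


def fit_4pl(curve: ELISACurve, min_r_squared: float = 0.9) -> FourPLFit:
    """Fit the 4PL by least squares; EC50 SE from the fit covariance.

    Starting values: bottom/top from the data extrema, EC50 from the
    concentration whose response is nearest half-maximal, hill = 1.
    Flat or non-monotone data fail the post-fit quality check and raise
    :class:`FitQualityError` carrying the achieved R².
    """
    x, y = curve.concentration, curve.response
    if len(x) < 5:
        raise ValidationError(
            f"4PL fit needs >= 5 concentration points, got {len(x)}"
        )
    b0, t0 = float(np.min(y)), float(np.max(y))
    half = (b0 + t0) / 2.0
    ec50_0 = float(x[np.argmin(np.abs(y - half))])
    p0 = [b0, t0, ec50_0, 1.0]
    bounds = ([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 50.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000,
                xtol=1e-14, ftol=1e-14,
            )
    except RuntimeError as exc:
        raise ConvergenceError(f"4PL fit failed to converge: {exc}") from exc
    yhat = four_pl(x, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    bottom, top, ec50, hill = (float(v) for v in popt)
    if ss_tot == 0 or r2 < min_r_squared:
        raise FitQualityError(
            f"dose-response data are flat or non-monotone "
            f"(R^2 = {r2:.3f} < {min_r_squared})",
            r_squared=r2,
        )
    if top < bottom:
        raise FitQualityError(
            f"fitted curve decreases with concentration "
            f"(top {top:.3g} < bottom {bottom:.3g}); expected an "
            f"increasing ELISA signal (R^2 = {r2:.3f})",
            r_squared=r2,
        )
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return FourPLFit(
        bottom=bottom, top=top, ec50=ec50, hill=hill,
        se_bottom=float(ses[0]), se_top=float(ses[1]),
        se_ec50=float(ses[2]), se_hill=float(ses[3]),
        r_squared=r2, n_points=len(x),
    )


def fold_difference(ec50_strong: float, ec50_weak: float) -> float:
    """Affinity fold-difference: EC50(weak binder) / EC50(strong binder)."""
    if ec50_strong <= 0 or ec50_weak <= 0:
        raise ValidationError("EC50 values must be > 0")
    return ec50_weak / ec50_strong


# --------------------------------------------------------------------------
# IHC positivity counting
# --------------------------------------------------------------------------

_POSITIVE = {"+"}
_NEGATIVE = {"-", "−"}  # ASCII hyphen-minus and typographic minus


def summarize_positivity(table: pd.DataFrame, column: str = "MUC1_16A") -> int:
    """Count '+' entries in a +/- staining column of an IHC table."""
    if column not in table.columns:
        raise ValidationError(
            f"column {column!r} not in table (have {list(table.columns)})"
        )
    count = 0
    for idx, value in table[column].items():
        symbol = str(value).strip()
        if symbol in _POSITIVE:
            count += 1
        elif symbol not in _NEGATIVE:
            raise ValidationError(
                f"row {idx}: unrecognized staining symbol {value!r} "
                f"(expected '+' or '-')"
            )
    return count
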