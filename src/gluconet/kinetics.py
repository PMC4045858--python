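"""Coupled-assay simulation, initial rates and Michaelis-Menten fitting.

The gluconokinase assay couples 6-phosphogluconate formation to its
oxidation by 6-phosphogluconate dehydrogenase (6PGDH), producing NADPH
1:1 and an absorbance increase at 340 nm. The simulator integrates the
two-step system

    d[S]/dt    = -Vmax [S] / (Km + [S])        (gluconokinase, co-substrate
                                                held saturating)
    d[6PG]/dt  =  Vmax [S] / (Km + [S]) - k_c [6PG]
    d[NADPH]/dt = k_c [6PG]

converts NADPH to absorbance through Beer-Lambert, and adds Gaussian
read noise. Initial rates come from the best early-time linear window
of a progress curve after conversion through an NADPH standard curve,
and v(S) data are fit to v = Vmax S / (Km + S) by nonlinear least
squares (lmfit), yielding Km, Vmax, kcat = Vmax/[E] and kcat/Km.

Concentrations are in uM, time in s, rates in uM/s throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

#: NADPH molar extinction at 340 nm, per M per cm
DEFAULT_EXTINCTION = 6220.0
#: effective optical path of a half-filled 96-well plate, cm
DEFAULT_PATH_LENGTH = 0.5


class FitError(RuntimeError):
    pass


@dataclass
class AssayConfig:
    """Coupled-assay setup (concentrations uM, times s)."""

    enzyme_conc: float = 0.25
    atp_conc: float = 1000.0
    nadp_conc: float = 650.0
    substrate_series: tuple[float, ...] = (100.0, 250.0, 500.0, 1000.0,
                                           2500.0, 5000.0, 10000.0)
    #: first-order rate of the 6PGDH coupling step, 1/s; a coupled
    #: assay needs the indicator step to be non-limiting, so the
    #: default lag (1/5 s) is negligible against the read interval
    coupling_rate: float = 5.0
    extinction_coefficient: float = DEFAULT_EXTINCTION
    path_length: float = DEFAULT_PATH_LENGTH
    read_interval: float = 1.0
    duration: float = 240.0
    blank_absorbance: float = 0.04

    def __post_init__(self) -> None:
        for name in ("atp_conc", "nadp_conc", "coupling_rate",
                     "extinction_coefficient", "path_length",
                     "read_interval", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.enzyme_conc < 0:
            raise ValueError("enzyme_conc must be non-negative")
        if any(s <= 0 for s in self.substrate_series):
            raise ValueError("substrate concentrations must be positive")

    @property
    def absorbance_per_uM(self) -> float:
        # extinction is per M; concentrations are uM
        return self.extinction_coefficient * 1e-6 * self.path_length

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 0.5 * self.read_interval,
                         self.read_interval)


@dataclass
class KineticParams:
    """Michaelis-Menten parameters with derived turnover quantities."""

    km: float                       # uM
    vmax: float                     # uM/s
    kcat: float = 0.0               # 1/s
    catalytic_efficiency: float = 0.0   # 1/(s*uM)
    r_squared: float = float("nan")
    standard_errors: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_km_vmax(cls, km: float, vmax: float,
                     enzyme_conc: float) -> "KineticParams":
        kcat = vmax / enzyme_conc
        return cls(km=km, vmax=vmax, kcat=kcat,
                   catalytic_efficiency=kcat / km)

    @classmethod
    def from_km_kcat(cls, km: float, kcat: float,
                     enzyme_conc: float) -> "KineticParams":
        return cls(km=km, vmax=kcat * enzyme_conc, kcat=kcat,
                   catalytic_efficiency=kcat / km)

    def rate(self, substrate: float | np.ndarray) -> float | np.ndarray:
        return self.vmax * substrate / (self.km + substrate)


@dataclass
class ProgressCurve:
    """One well: absorbance at 340 nm over time at a labelled substrate."""

    time: np.ndarray
    absorbance_340: np.ndarray
    substrate_label: float
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance_340 = np.asarray(self.absorbance_340, dtype=float)
        if len(self.time) != len(self.absorbance_340):
            raise ValueError("time and absorbance lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


# ---------------------------------------------------------------------------
# simulation


def _integrate_well(params: KineticParams, config: AssayConfig,
                    s0: float) -> np.ndarray:
    """Noise-free NADPH concentration (uM) at the configured read times."""
    times = config.times()
    if config.enzyme_conc == 0 or params.vmax == 0:
        return np.zeros_like(times)
    k_c = config.coupling_rate

    def rhs(_t, y):
        s, pg = y
        v1 = params.vmax * s / (params.km + s) if s > 0 else 0.0
        return (-v1, v1 - k_c * pg)

    sol = solve_ivp(rhs, (times[0], times[-1]), (s0, 0.0), t_eval=times,
                    method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"assay integration failed: {sol.message}")
    s, pg = sol.y
    nadph = s0 - s - pg         # 1:1 stoichiometry, conservation of carbon
    return np.clip(nadph, 0.0, None)


def simulate_assay(true_params: KineticParams, config: AssayConfig,
                   noise_sd: float = 0.0, seed: int | None = None,
                   n_replicates: int = 1) -> list[ProgressCurve]:
    """Simulate progress curves for every substrate concentration.

    ``noise_sd`` is the per-read Gaussian absorbance noise (AU). The
    coupling step should be fast relative to turnover; a lag constant
    exceeding 5 % of the assay duration triggers a warning since the
    early-time window then underestimates the gluconokinase rate.
    """
    if not (np.isfinite(true_params.km) and np.isfinite(true_params.vmax)):
        raise ValueError("kinetic parameters must be finite")
    if true_params.km <= 0 or true_params.vmax < 0:
        raise ValueError("Km must be positive and Vmax non-negative")
    if 1.0 / config.coupling_rate > 0.05 * config.duration:
        warnings.warn(
            "6PGDH coupling lag exceeds 5% of the assay duration; "
            "initial rates will lag the gluconokinase rate", stacklevel=2)
    rng = np.random.default_rng(seed)
    times = config.times()
    curves = []
    for s0 in config.substrate_series:
        nadph = _integrate_well(true_params, config, s0)
        clean = config.blank_absorbance + config.absorbance_per_uM * nadph
        for rep in range(n_replicates):
            noisy = clean if noise_sd == 0 else \
                clean + rng.normal(0.0, noise_sd, size=clean.shape)
            curves.append(ProgressCurve(time=times, absorbance_340=noisy,
                                        substrate_label=s0, replicate=rep))
    return curves


# ---------------------------------------------------------------------------
# initial rates


def initial_rate(curve: ProgressCurve, standard_slope: float,
                 standard_intercept: float = 0.0,
                 min_points: int = 10, depletion_fraction: float = 0.10,
                 r2_warn: float = 0.99) -> float:
    """Initial NADPH production rate (uM/s) from a progress curve.

    Absorbance is converted to NADPH through the standard curve
    ``A = slope * [NADPH] + intercept``; the rate is the slope of the
    best-R^2 contiguous window of at least ``min_points`` reads lying
    within the first ``depletion_fraction`` of substrate conversion
    (falling back to the earliest window when conversion is too fast to
    leave one). Any ``min_points`` >= 5 is supported; the default of 10
    balances read noise against substrate-depletion bias at the default
    1 s read interval. Warns when no candidate window reaches
    ``r2_warn``.
    """
    if standard_slope <= 0:
        raise ValueError("standard curve slope must be positive")
    if len(curve.time) < min_points:
        raise ValueError(
            f"need at least {min_points} points, got {len(curve.time)}")
    nadph = (curve.absorbance_340 - standard_intercept) / standard_slope
    nadph = nadph - nadph[0]    # blank subtraction at t0

    limit = depletion_fraction * curve.substrate_label
    within = np.nonzero(nadph <= limit)[0]
    last = int(within[-1]) + 1 if len(within) else min_points
    last = max(last, min_points)

    t = curve.time[:last]
    y = nadph[:last]
    # All contiguous windows [a, b) with a small start offset (to step
    # over the coupling lag) scored by linear-fit R^2 via prefix sums.
    T = np.concatenate(([0.0], np.cumsum(t)))
    T2 = np.concatenate(([0.0], np.cumsum(t * t)))
    Y = np.concatenate(([0.0], np.cumsum(y)))
    Y2 = np.concatenate(([0.0], np.cumsum(y * y)))
    TY = np.concatenate(([0.0], np.cumsum(t * y)))
    candidates = []   # (r2, start, stop, slope)
    max_start = min(20, len(t) - min_points)
    for a in range(max_start + 1):
        b = np.arange(a + min_points, len(t) + 1)
        n = b - a
        st = T[b] - T[a]
        stt = T2[b] - T2[a]
        sy = Y[b] - Y[a]
        syy = Y2[b] - Y2[a]
        sty = TY[b] - TY[a]
        cov = n * sty - st * sy
        var_t = n * stt - st * st
        var_y = n * syy - sy * sy
        slope = cov / var_t
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(var_y > 0, cov * cov / (var_t * var_y), 0.0)
        k = int(np.argmax(r2))
        candidates.append((float(r2[k]), a, int(b[k]), float(slope[k])))
    best_r2 = max(c[0] for c in candidates)
    # substrate depletion makes *later* windows ever straighter, so a
    # pure R^2 argmax drifts away from t = 0; among windows whose fit
    # quality is indistinguishable (within 1e-4) take the earliest
    r2, _, _, slope = min((c for c in candidates if c[0] >= best_r2 - 1e-4),
                          key=lambda c: (c[1], c[2]))
    if r2 < r2_warn and slope != 0:
        warnings.warn(
            f"best initial-rate window has R^2 = {r2:.3f} < {r2_warn}",
            stacklevel=2)
    return float(slope)


# ---------------------------------------------------------------------------
# Michaelis-Menten fitting


def fit_mm(rates: list[tuple[float, float]] | np.ndarray,
           enzyme_conc: float) -> KineticParams:
    """Nonlinear least-squares Michaelis-Menten fit of (S, v) data.

    Requires >= 4 distinct substrate concentrations. Initial guesses:
    Vmax0 = max observed rate, Km0 = substrate at half-maximal rate.
    Warns when the fitted Km falls outside the sampled substrate range
    (the estimate is then an extrapolation).
    """
    from lmfit import Model

    data = np.asarray(rates, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("rates must be (substrate, rate) pairs")
    s, v = data[:, 0], data[:, 1]
    if len(np.unique(s)) < 4:
        raise ValueError("need rates at >= 4 distinct substrate concentrations")

    vmax0 = float(np.max(v))
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])
    model = Model(lambda S, vmax, km: vmax * S / (km + S),
                  independent_vars=["S"])
    params = model.make_params(vmax=dict(value=vmax0, min=0),
                               km=dict(value=max(km0, 1e-6), min=1e-9))
    result = model.fit(v, params, S=s)
    if not result.success:
        raise FitError(f"Michaelis-Menten fit did not converge: {result.message}")

    km = float(result.params["km"].value)
    vmax = float(result.params["vmax"].value)
    if not s.min() <= km <= s.max():
        warnings.warn(
            f"fitted Km {km:.3g} uM lies outside the sampled range "
            f"[{s.min():.3g}, {s.max():.3g}] uM", stacklevel=2)
    sst = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(result.chisqr) / sst if sst > 0 else float("nan")
    errors = {
        name: float(result.params[name].stderr)
        for name in ("km", "vmax")
        if result.params[name].stderr is not None
    }
    fitted = KineticParams.from_km_vmax(km, vmax, enzyme_conc)
    fitted.r_squared = r2
    fitted.standard_errors = errors
    return fitted


def double_reciprocal(rates: list[tuple[float, float]] | np.ndarray) -> np.ndarray:
    """Lineweaver-Burk transform: columns (1/S, 1/v), for plotting."""
    data = np.asarray(rates, dtype=float)
    if np.any(data == 0):
        raise ValueError("double-reciprocal transform undefined at zero")
    return 1.0 / data
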