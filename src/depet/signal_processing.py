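"""Voltage-clamp fluorometry preprocessing.

Turns raw fluorescence/current/voltage sweeps and quencher titrations into
the observables the distance inversion consumes:

* photobleach correction by subtracting an exponential fit to a no-pulse
  reference recording;
* Boltzmann fit of voltage-evoked fluorescence deflections,
  dF = dF_total / (1 + exp[(zF/RT)(V1/2 - Vm)]) + dF_min;
* macroscopic conductance G = I/(Vm - EK) and its double-Boltzmann fit with
  G_max the exact sum of the two component maxima;
* conductance normalisation dF/G (removes expression-level variation);
* Stern-Volmer constant K_SV from F0/F vs quencher concentration.

Voltages in mV, currents in nA, concentrations in M, temperature in K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SweepRecord",
    "BoltzmannFit",
    "ConductanceFit",
    "SternVolmerTitration",
    "bleach_correct",
    "extract_deltaF",
    "fit_deltaF_boltzmann",
    "conductance_from_iv",
    "fit_g_double_boltzmann",
    "normalize_deltaF",
    "stern_volmer_ksv",
]

log = logging.getLogger(__name__)

FARADAY = 96485.332  # C / mol
GAS_CONSTANT = 8.314462  # J / (mol K)
DEFAULT_TEMPERATURE = 294.0  # K


@dataclass
class SweepRecord:
    """One voltage-clamp fluorometry sweep (aligned, equal-length arrays)."""

    time: np.ndarray  # ms
    fluorescence: np.ndarray  # arbitrary units
    current: np.ndarray  # nA
    voltage: np.ndarray  # mV
    e_k: float = -90.0  # mV, K+ equilibrium potential
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("time", "fluorescence", "current", "voltage"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        if not all(len(getattr(self, f)) == n for f in ("fluorescence", "current", "voltage")):
            raise ValueError("sweep arrays must have equal length")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class BoltzmannFit:
    """Single-Boltzmann fit of dF vs voltage."""

    delta_f_total: float
    delta_f_min: float
    v_half: float  # mV
    z: float  # effective valence (elementary charges)
    temperature: float = DEFAULT_TEMPERATURE
    residual_rms: float = 0.0

    def __call__(self, v_m):
        return _boltzmann(
            np.asarray(v_m, dtype=float),
            self.delta_f_total,
            self.v_half,
            self.z,
            self.delta_f_min,
            self.temperature,
        )


@dataclass
class ConductanceFit:
    """Double-Boltzmann fit of macroscopic conductance vs voltage."""

    g_max_components: tuple[float, float]
    v_half_components: tuple[float, float]
    z_components: tuple[float, float]
    temperature: float = DEFAULT_TEMPERATURE
    residual_rms: float = 0.0

    @property
    def g_max(self) -> float:
        # G_max is by definition the exact sum of the component maxima
        return self.g_max_components[0] + self.g_max_components[1]

    def __call__(self, v_m):
        v = np.asarray(v_m, dtype=float)
        out = np.zeros_like(v)
        for g, vh, z in zip(self.g_max_components, self.v_half_components, self.z_components):
            out = out + _boltzmann(v, g, vh, z, 0.0, self.temperature)
        return out


@dataclass
class SternVolmerTitration:
    """Linear Stern-Volmer analysis: F0/F = 1 + K_SV [Q]."""

    quencher_concentrations: np.ndarray  # M
    f0_over_f: np.ndarray
    ksv: float  # 1/M
    intercept: float
    r_squared: float = float("nan")


def _boltzmann(v_m, amplitude, v_half, z, offset, temperature):
    zf_rt = z * FARADAY / (GAS_CONSTANT * temperature)
    # voltages are mV; F/RT expects volts; exponent clipped against overflow
    arg = np.clip(zf_rt * (v_half - v_m) * 1e-3, -700.0, 700.0)
    return amplitude / (1.0 + np.exp(arg)) + offset


def bleach_correct(sweep: SweepRecord, reference_sweep: SweepRecord) -> SweepRecord:
    """Remove photobleaching using a no-pulse reference recording.

    A single exponential (amplitude, tau, offset) is least-squares fit to the
    reference fluorescence and its time course (minus the fitted offset,
    which carries the reference's own baseline) is subtracted from the sweep.
    """
    if len(reference_sweep.time) != len(sweep.time):
        raise ValueError("reference must share the sweep's sampling")
    t = reference_sweep.time - reference_sweep.time[0]
    f_ref = reference_sweep.fluorescence

    span = float(f_ref.max() - f_ref.min())
    tau0 = max(t[-1] / 3.0, 1e-6)
    amp0 = f_ref[0] - f_ref[-1] if span > 0 else 0.0

    def model(params, tt):
        a, tau, c = params
        return a * np.exp(-tt / tau) + c

    def residual(params):
        return model(params, t) - f_ref

    sol = optimize.least_squares(
        residual,
        x0=[amp0, tau0, f_ref[-1]],
        bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"bleach reference fit failed: {sol.message}")
    amp, tau, offset = sol.x
    log.debug("bleach fit: amplitude=%.4g tau=%.4g ms offset=%.4g", amp, tau, offset)
    corrected = sweep.fluorescence - amp * np.exp(-(sweep.time - sweep.time[0]) / tau)
    return replace(sweep, fluorescence=corrected)


def extract_deltaF(
    sweep: SweepRecord,
    pulse_start_ms: float,
    pulse_end_ms: float,
    plateau_fraction: float = 0.2,
) -> float:
    """Voltage-evoked fluorescence deflection amplitude of one sweep.

    Measured as the mean of the last ``plateau_fraction`` of the pulse minus
    the pre-pulse baseline mean (the steady part of the deflection, avoiding
    the rising phase).
    """
    t = sweep.time
    pulse = (t >= pulse_start_ms) & (t < pulse_end_ms)
    baseline = t < pulse_start_ms
    if not pulse.any() or not baseline.any():
        raise ValueError("pulse window leaves no baseline or no pulse samples")
    t_plateau = pulse_end_ms - plateau_fraction * (pulse_end_ms - pulse_start_ms)
    plateau = pulse & (t >= t_plateau)
    return float(sweep.fluorescence[plateau].mean() - sweep.fluorescence[baseline].mean())


def fit_deltaF_boltzmann(
    delta_f,
    voltages,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of dF amplitudes vs test potential."""
    y = np.asarray(delta_f, dtype=float)
    v = np.asarray(voltages, dtype=float)
    if len(y) != len(v):
        raise ValueError("delta_f and voltages must have equal length")
    if len(v) < 5:
        raise ValueError("need at least 5 test potentials spanning the transition")

    span = float(y.max() - y.min())
    p0 = [span if span else 1.0, float(np.median(v)), 1.0, float(y.min())]

    def residual(p):
        return _boltzmann(v, p[0], p[1], p[2], p[3], temperature) - y

    sol = optimize.least_squares(residual, p0, xtol=1e-13, ftol=1e-13, max_nfev=5000)
    if not sol.success:
        raise RuntimeError(f"Boltzmann fit did not converge: {sol.message}")
    total, v_half, z, f_min = sol.x
    if z < 0:  # (amplitude, z) -> (-amplitude, -z) is the same curve shifted; normalise z > 0
        total, z, f_min = -total, -z, f_min + total
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return BoltzmannFit(
        delta_f_total=float(total),
        delta_f_min=float(f_min),
        v_half=float(v_half),
        z=float(z),
        temperature=temperature,
        residual_rms=rms,
    )


def conductance_from_iv(current, voltage, e_k: float, guard_mv: float = 0.5):
    """Macroscopic conductance G = I/(Vm - EK), in uS for nA and mV inputs.

    Points within ``guard_mv`` of the reversal potential are excluded (the
    division blows up there); returns (conductances, kept_voltages).
    """
    i_arr = np.asarray(current, dtype=float)
    v_arr = np.asarray(voltage, dtype=float)
    if i_arr.shape != v_arr.shape:
        raise ValueError("current and voltage must have equal shape")
    keep = np.abs(v_arr - e_k) >= guard_mv
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("conductance_from_iv: dropped %d point(s) within %.2f mV of E_K", n_dropped, guard_mv)
    return i_arr[keep] / (v_arr[keep] - e_k), v_arr[keep]


def fit_g_double_boltzmann(
    conductances,
    voltages,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ConductanceFit:
    """Fit conductance-voltage data with the sum of two Boltzmann components."""
    g = np.asarray(conductances, dtype=float)
    v = np.asarray(voltages, dtype=float)
    if len(g) != len(v):
        raise ValueError("conductances and voltages must have equal length")
    if len(v) < 8:
        raise ValueError("need at least 8 voltages for a two-component fit")

    g_top = float(g.max()) if g.max() > 0 else 1.0
    v_lo, v_hi = np.percentile(v, [25, 75])

    def residual(p):
        g1, vh1, z1, g2, vh2, z2 = p
        model = _boltzmann(v, g1, vh1, z1, 0.0, temperature) + _boltzmann(
            v, g2, vh2, z2, 0.0, temperature
        )
        return model - g

    best = None
    # two starts: balanced split and single-component-dominant
    for frac in (0.5, 0.95):
        p0 = [frac * g_top, v_lo, 1.0, (1 - frac) * g_top, v_hi, 1.0]
        sol = optimize.least_squares(
            residual,
            p0,
            bounds=([0, -np.inf, 1e-3, 0, -np.inf, 1e-3], np.inf),
            xtol=1e-13,
            ftol=1e-13,
            max_nfev=10000,
        )
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    sol = best[1]
    if not sol.success and not math.isfinite(best[0]):
        raise RuntimeError(f"double-Boltzmann fit did not converge: {sol.message}")
    g1, vh1, z1, g2, vh2, z2 = sol.x
    # order components by g_max, largest first
    if g2 > g1:
        g1, vh1, z1, g2, vh2, z2 = g2, vh2, z2, g1, vh1, z1
    return ConductanceFit(
        g_max_components=(float(g1), float(g2)),
        v_half_components=(float(vh1), float(vh2)),
        z_components=(float(z1), float(z2)),
        temperature=temperature,
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


def normalize_deltaF(fit: BoltzmannFit, g_fit: ConductanceFit) -> float:
    """Conductance-normalised fluorescence change, dF_total / G_max."""
    if g_fit.g_max <= 0:
        raise ValueError("G_max must be positive")
    return fit.delta_f_total / g_fit.g_max


def stern_volmer_ksv(concentrations, fluorescence, absorbance) -> SternVolmerTitration:
    """Stern-Volmer constant from a quencher titration.

    Fluorescence is normalised by absorbance (corrects for fluorophore
    amount); F0 is the zero-quencher point; K_SV is the slope of the linear
    regression of F0/F on concentration.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if not (len(c) == len(f) == len(a)):
        raise ValueError("titration arrays must have equal length")
    if len(c) < 3:
        raise ValueError("need at least 3 concentrations for a Stern-Volmer fit")
    if np.any(a <= 0):
        raise ValueError("absorbances must be positive")
    if not np.any(c == 0):
        raise ValueError("titration must include a zero-quencher point")
    f_norm = f / a
    f0 = float(np.mean(f_norm[c == 0]))
    ratio = f0 / f_norm
    res = stats.linregress(c, ratio)
    return SternVolmerTitration(
        quencher_concentrations=c,
        f0_over_f=ratio,
        ksv=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
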