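"""Fluorophore-Distance-Quencher (FDQ) functions.

An FDQ function gives the probability that a Cys-conjugated fluorophore is
quenched by a tryptophan as a function of the distance separating their
anchor atoms. It is built in two steps:

1.  The fluorophore and quencher radial densities (``f`` and ``q``,
    probability per concentric spherical shell about their anchors) are
    combined by summing, over every pair of occupied shells, the product of
    the shell probabilities weighted twice by the ratio of the shell-shell
    intersection volume to each shell's own volume:

        P(X, d) = sum_{R,r} [V_Kk(d,R,r)/V_K(R)] f(X,K)
                            x [V_Kk(d,R,r)/V_k(r)] q(k)

2.  The resulting discrete curve is fit by an empirical sum of up to two
    exponentials and six Gaussians,

        FDQ(X, d) = sum_i alpha_i exp(-d/delta_i)
                    + sum_j A_j / sqrt(2 pi sigma_j)
                          x exp(-(d - mu_j)^2 / (2 sigma_j^2)),

    so that downstream curve fitting has a smooth, cheap closed form.

Fluorophores of different quenching efficiency can be put on a common scale
by multiplying the whole function by the ratio of their Stern-Volmer
constants (``scale_by_ksv``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .conformer_density import RadialDensity
from .geometry import shell_volume

__all__ = [
    "QuenchCurve",
    "FDQModel",
    "quench_probability_curve",
    "mix_isomers",
    "fit_fdq",
    "eval_fdq",
    "scale_by_ksv",
    "save_fdq_table",
    "load_fdq_table",
]

_ANCHOR_PAIRS = ("aa", "ab", "ba", "bb")


@dataclass
class QuenchCurve:
    """Discrete quenching probability vs anchor-anchor distance."""

    distances: np.ndarray  # grid of d values (Angstrom, step = bin width)
    probabilities: np.ndarray
    fluorophore_tag: str = ""
    anchor_pair: str = "aa"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.distances.shape != self.probabilities.shape:
            raise ValueError("distances and probabilities must have equal shape")
        if self.anchor_pair not in _ANCHOR_PAIRS:
            raise ValueError(f"anchor_pair must be one of {_ANCHOR_PAIRS}")


@dataclass
class FDQModel:
    """Empirical exponential + Gaussian parameterisation of a quench curve.

    Evaluations are clipped to >= 0 and multiplied by ``ksv_scale`` (the
    Stern-Volmer normalisation factor, 1 for the reference fluorophore).
    """

    exp_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    exp_length_constants: np.ndarray = field(default_factory=lambda: np.empty(0))
    gauss_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    gauss_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    gauss_sds: np.ndarray = field(default_factory=lambda: np.empty(0))
    fluorophore_tag: str = ""
    anchor_pair: str = "aa"
    ksv_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "exp_amplitudes",
            "exp_length_constants",
            "gauss_amplitudes",
            "gauss_means",
            "gauss_sds",
        ):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if len(self.exp_amplitudes) != len(self.exp_length_constants):
            raise ValueError("exponential amplitude/length-constant count mismatch")
        if not (len(self.gauss_amplitudes) == len(self.gauss_means) == len(self.gauss_sds)):
            raise ValueError("Gaussian parameter array length mismatch")
        if np.any(self.exp_length_constants <= 0):
            raise ValueError("exponential length constants must be positive")
        if np.any(self.gauss_sds <= 0):
            raise ValueError("Gaussian standard deviations must be positive")

    def __call__(self, d):
        return eval_fdq(self, d)

    def derivative(self, d):
        """d(FDQ)/dd, analytic (used for fast Jacobians in distance fitting).

        The derivative of the unclipped sum; valid wherever the evaluation is
        positive (clipping only engages where the sum goes negative).
        """
        d = np.asarray(d, dtype=float)
        out = np.zeros_like(d)
        for a, dl in zip(self.exp_amplitudes, self.exp_length_constants):
            out = out - (a / dl) * np.exp(-d / dl)
        for A, mu, sd in zip(self.gauss_amplitudes, self.gauss_means, self.gauss_sds):
            g = (A / math.sqrt(2.0 * math.pi * sd)) * np.exp(-((d - mu) ** 2) / (2.0 * sd**2))
            out = out - g * (d - mu) / sd**2
        return self.ksv_scale * out


def _eval_components(params, n_exp: int, n_gauss: int, d: np.ndarray) -> np.ndarray:
    """Evaluate the raw (unclipped, unscaled) exponential + Gaussian sum."""
    out = np.zeros_like(d)
    k = 0
    for _ in range(n_exp):
        a, dl = params[k], params[k + 1]
        out = out + a * np.exp(-d / dl)
        k += 2
    for _ in range(n_gauss):
        A, mu, sd = params[k], params[k + 1], params[k + 2]
        out = out + (A / np.sqrt(2.0 * np.pi * sd)) * np.exp(-((d - mu) ** 2) / (2.0 * sd**2))
        k += 3
    return out


def eval_fdq(model: FDQModel, d):
    """FDQ evaluation: ksv_scale * max(0, sum of terms). Accepts scalars or arrays."""
    d_arr = np.asarray(d, dtype=float)
    scalar = d_arr.ndim == 0
    d_arr = np.atleast_1d(d_arr)
    if np.any(d_arr < 0):
        raise ValueError("distance must be non-negative")
    out = np.zeros_like(d_arr)
    for a, dl in zip(model.exp_amplitudes, model.exp_length_constants):
        out = out + a * np.exp(-d_arr / dl)
    for A, mu, sd in zip(model.gauss_amplitudes, model.gauss_means, model.gauss_sds):
        out = out + (A / math.sqrt(2.0 * math.pi * sd)) * np.exp(
            -((d_arr - mu) ** 2) / (2.0 * sd**2)
        )
    out = model.ksv_scale * np.clip(out, 0.0, None)
    return float(out[0]) if scalar else out


def _ball_overlap_np(d, a, b):
    """Vectorised clamped two-ball overlap volume (see geometry.ball_overlap_volume)."""
    d = np.asarray(d, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.zeros(np.broadcast(d, a, b).shape)
    valid = (a > 0) & (b > 0) & (d < a + b)
    contained = valid & (d <= np.abs(a - b))
    rmin = np.minimum(np.broadcast_to(a, out.shape), np.broadcast_to(b, out.shape))
    out[contained] = (4.0 * np.pi / 3.0) * rmin[contained] ** 3
    lens = valid & ~contained
    if np.any(lens):
        chi = np.broadcast_to(d, out.shape)[lens]
        psi = np.broadcast_to(a, out.shape)[lens]
        omega = np.broadcast_to(b, out.shape)[lens]
        out[lens] = (
            np.pi
            * (psi + omega - chi) ** 2
            * (chi**2 + 2 * chi * psi - 3 * psi**2 + 2 * chi * omega - 3 * omega**2 + 6 * psi * omega)
            / (12.0 * chi)
        )
    return out


def _shell_intersection_np(d: float, R, r, dr: float):
    """Vectorised shell-shell intersection volume at scalar separation d."""
    if d < 1e-9:
        # concentric: overlap of the radial intervals (R-dr, R] and (r-dr, r]
        lo = np.maximum(R - dr, r - dr)
        hi = np.minimum(R, r)
        return (4.0 * np.pi / 3.0) * np.clip(hi**3 - lo**3, 0.0, None)
    v = (
        _ball_overlap_np(d, R, r)
        - _ball_overlap_np(d, R - dr, r)
        - _ball_overlap_np(d, R, r - dr)
        + _ball_overlap_np(d, R - dr, r - dr)
    )
    return np.clip(v, 0.0, None)


def quench_probability_curve(f: RadialDensity, q: RadialDensity) -> QuenchCurve:
    """Combine fluorophore and quencher radial densities into a quench curve.

    The grid runs from 0 to the sum of the two density supports in steps of
    the shared bin width.
    """
    if not math.isclose(f.bin_width, q.bin_width, rel_tol=0, abs_tol=1e-12):
        raise ValueError(f"bin widths differ: {f.bin_width} vs {q.bin_width}")
    dr = f.bin_width

    f_idx = np.nonzero(f.probabilities)[0]
    q_idx = np.nonzero(q.probabilities)[0]
    R = (f_idx + 1) * dr  # shell maximal radii
    r = (q_idx + 1) * dr
    fp = f.probabilities[f_idx]
    qp = q.probabilities[q_idx]
    v_K = np.array([shell_volume(rho, dr) for rho in R])
    v_k = np.array([shell_volume(rho, dr) for rho in r])

    d_max = f.support_radius + q.support_radius
    n_pts = int(round(d_max / dr)) + 1
    distances = dr * np.arange(n_pts)

    Rg, rg = np.meshgrid(R, r, indexing="ij")
    weight = (fp[:, None] * qp[None, :]) / (v_K[:, None] * v_k[None, :])
    probs = np.empty(n_pts)
    for i, d in enumerate(distances):
        v = _shell_intersection_np(float(d), Rg, rg, dr)
        probs[i] = float(np.sum(weight * v * v))

    anchor_pair = ("a" if f.anchor_kind == "Ca" else "b") + (
        "a" if q.anchor_kind == "Ca" else "b"
    )
    return QuenchCurve(
        distances=distances,
        probabilities=probs,
        fluorophore_tag="",
        anchor_pair=anchor_pair,
    )


def mix_isomers(curve_a: QuenchCurve, curve_b: QuenchCurve) -> QuenchCurve:
    """Pointwise average of two stereoisomer quench curves (their 50/50 mix)."""
    if curve_a.anchor_pair != curve_b.anchor_pair:
        raise ValueError("cannot mix curves with different anchor pairs")
    if curve_a.distances.shape != curve_b.distances.shape or not np.allclose(
        curve_a.distances, curve_b.distances, atol=1e-12
    ):
        raise ValueError("cannot mix curves on different distance grids")
    tag_a, tag_b = curve_a.fluorophore_tag, curve_b.fluorophore_tag
    return QuenchCurve(
        distances=curve_a.distances.copy(),
        probabilities=0.5 * (curve_a.probabilities + curve_b.probabilities),
        fluorophore_tag=f"{tag_a}/{tag_b}" if tag_a != tag_b else tag_a,
        anchor_pair=curve_a.anchor_pair,
    )


class FDQFitError(RuntimeError):
    """Raised when no component count reaches the residual threshold."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(message)
        self.best_residual = best_residual


def _candidate_counts(max_exp: int, max_gauss: int):
    combos = [
        (e, g)
        for e in range(max_exp + 1)
        for g in range(max_gauss + 1)
        if e + g > 0
    ]
    combos.sort(key=lambda eg: (eg[0] + eg[1], eg[0]))
    return combos


def _greedy_initial_params(d, y, n_exp: int, n_gauss: int):
    """Seed components one at a time against the running residual."""
    params: list[float] = []
    resid = y.copy()
    d_span = max(d[-1] - d[0], 1.0)
    for _ in range(n_exp):
        a0 = max(resid[0], 1e-6 * max(y.max(), 1e-30))
        params += [a0, 0.25 * d_span]
        resid = resid - a0 * np.exp(-d / (0.25 * d_span))
    for _ in range(n_gauss):
        j = int(np.argmax(resid))
        mu0 = d[j]
        peak = max(resid[j], 1e-6 * max(y.max(), 1e-30))
        sd0 = max(0.05 * d_span, 0.2)
        A0 = peak * math.sqrt(2.0 * math.pi * sd0)
        params += [A0, mu0, sd0]
        resid = resid - (A0 / math.sqrt(2.0 * math.pi * sd0)) * np.exp(
            -((d - mu0) ** 2) / (2.0 * sd0**2)
        )
    return np.array(params)


def fit_fdq(
    curve: QuenchCurve,
    max_exp: int = 2,
    max_gauss: int = 6,
    rel_tol: float = 1e-3,
) -> FDQModel:
    """Fit the exponential + Gaussian parameterisation to a quench curve.

    Components are added in order of increasing total count until the RMS
    residual drops below ``rel_tol`` of the curve maximum (nonnegative
    amplitudes throughout). An all-zero curve yields the zero model.
    """
    d = curve.distances
    y = curve.probabilities
    y_max = float(y.max()) if y.size else 0.0
    if y_max == 0.0:
        return FDQModel(
            exp_amplitudes=np.empty(0),
            exp_length_constants=np.empty(0),
            gauss_amplitudes=np.empty(0),
            gauss_means=np.empty(0),
            gauss_sds=np.empty(0),
            fluorophore_tag=curve.fluorophore_tag,
            anchor_pair=curve.anchor_pair,
        )
    if np.count_nonzero(y) < 20:
        raise ValueError("curve needs at least 20 nonzero points to fit")

    best = None  # (rms, n_exp, n_gauss, params)
    for n_exp, n_gauss in _candidate_counts(max_exp, max_gauss):
        p0 = _greedy_initial_params(d, y, n_exp, n_gauss)
        lower, upper = [], []
        for _ in range(n_exp):
            lower += [0.0, 1e-3]
            upper += [np.inf, np.inf]
        for _ in range(n_gauss):
            lower += [0.0, 0.0, 1e-3]
            upper += [np.inf, d[-1] + 1.0, np.inf]
        p0 = np.clip(p0, np.array(lower) + 1e-12, None)

        def residual(p, n_exp=n_exp, n_gauss=n_gauss):
            return _eval_components(p, n_exp, n_gauss, d) - y

        try:
            sol = least_squares(
                residual, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:
            continue
        rms = float(np.sqrt(np.mean(residual(sol.x) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, n_exp, n_gauss, sol.x)
        if rms < rel_tol * y_max:
            break

    if best is None:
        raise FDQFitError("no component count converged", best_residual=math.inf)
    rms, n_exp, n_gauss, p = best
    if rms >= rel_tol * y_max:
        raise FDQFitError(
            f"best RMS residual {rms:.3e} exceeds {rel_tol:.1e} x curve max {y_max:.3e}",
            best_residual=rms,
        )
    k = 0
    ea, el, ga, gm, gs = [], [], [], [], []
    for _ in range(n_exp):
        ea.append(p[k]); el.append(p[k + 1]); k += 2
    for _ in range(n_gauss):
        ga.append(p[k]); gm.append(p[k + 1]); gs.append(p[k + 2]); k += 3
    return FDQModel(
        exp_amplitudes=np.array(ea),
        exp_length_constants=np.array(el),
        gauss_amplitudes=np.array(ga),
        gauss_means=np.array(gm),
        gauss_sds=np.array(gs),
        fluorophore_tag=curve.fluorophore_tag,
        anchor_pair=curve.anchor_pair,
    )


def scale_by_ksv(model: FDQModel, ksv: float, ksv_reference: float) -> FDQModel:
    """Rescale an FDQ by the ratio of Stern-Volmer constants ksv/ksv_reference."""
    if ksv <= 0 or ksv_reference <= 0:
        raise ValueError("Stern-Volmer constants must be positive")
    return FDQModel(
        exp_amplitudes=model.exp_amplitudes.copy(),
        exp_length_constants=model.exp_length_constants.copy(),
        gauss_amplitudes=model.gauss_amplitudes.copy(),
        gauss_means=model.gauss_means.copy(),
        gauss_sds=model.gauss_sds.copy(),
        fluorophore_tag=model.fluorophore_tag,
        anchor_pair=model.anchor_pair,
        ksv_scale=model.ksv_scale * ksv / ksv_reference,
    )


def save_fdq_table(models, path) -> None:
    """Write a set of FDQ models to JSON (one entry per fluorophore x anchor pair)."""
    rows = []
    for m in models:
        rows.append(
            {
                "fluorophore_tag": m.fluorophore_tag,
                "anchor_pair": m.anchor_pair,
                "exp_amplitudes": m.exp_amplitudes.tolist(),
                "exp_length_constants": m.exp_length_constants.tolist(),
                "gauss_amplitudes": m.gauss_amplitudes.tolist(),
                "gauss_means": m.gauss_means.tolist(),
                "gauss_sds": m.gauss_sds.tolist(),
                "ksv_scale": m.ksv_scale,
            }
        )
    Path(path).write_text(json.dumps({"fdq_models": rows}, indent=1))


def load_fdq_table(path) -> list[FDQModel]:
    """Read a set of FDQ models from JSON written by :func:`save_fdq_table`."""
    data = json.loads(Path(path).read_text())
    if "fdq_models" not in data:
        raise ValueError(f"{path}: missing 'fdq_models' key")
    models = []
    for row in data["fdq_models"]:
        try:
            models.append(
                FDQModel(
                    exp_amplitudes=np.array(row["exp_amplitudes"], dtype=float),
                    exp_length_constants=np.array(row["exp_length_constants"], dtype=float),
                    gauss_amplitudes=np.array(row["gauss_amplitudes"], dtype=float),
                    gauss_means=np.array(row["gauss_means"], dtype=float),
                    gauss_sds=np.array(row["gauss_sds"], dtype=float),
                    fluorophore_tag=row["fluorophore_tag"],
                    anchor_pair=row.get("anchor_pair", "aa"),
                    ksv_scale=float(row.get("ksv_scale", 1.0)),
                )
            )
        except KeyError as exc:
            raise ValueError(f"{path}: FDQ table row missing field {exc}") from exc
    return models
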