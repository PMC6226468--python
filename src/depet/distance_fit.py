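"""The DEPET inverse problem.

Given conductance-normalised fluorescence changes (dF/G) from several
fluorophores of different linker length conjugated at one site, and the FDQ
function of each fluorophore, recover the distances between the labelled Cys
C-alpha and the quenching Trp anchor in the resting and active states.

The forward model per fluorophore X is

    dF_X = [FDQ_aa(X, d_R) - FDQ_aa(X, d_A)] * c

with c > 0 a conversion coefficient shared across fluorophores. Experimental
variability is propagated by bootstrap: replicates are resampled with
replacement per fluorophore to build ``n_bootstrap`` sample sets; each set is
fit by nonlinear least squares started from every point of a cartesian seed
grid (five increments per free parameter by default) and only the least-error
fit per set is kept. The retained per-set solutions form the distributions
from which means and 95% percentile confidence intervals are reported.

When C-alpha-C-beta (``ab``) FDQ functions are supplied as well, the fit
stacks both equation systems with a common c (five free parameters) and
discards bootstrap solutions whose alpha-alpha / alpha-beta distances differ
by more than one C-C bond (1.54 Angstrom) in either state — the Trp C-beta
cannot stray further than its bond to the C-alpha allows.

``DepetModel`` / ``DepetResults`` follow the familiar model/results split:
construct the model from data, call ``fit()``, inspect the results object.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fdq import FDQModel
from .geometry import CC_BOND, angle_from_distances, planar_coordinates

__all__ = [
    "QuenchingDataset",
    "SeedGrid",
    "DepetModel",
    "DepetResults",
    "forward_deltaF",
    "bootstrap_resample",
    "build_seed_grid",
    "fit_single_pair",
    "fit_dual_pair",
    "run_depet",
]

DEFAULT_DISTANCE_BOUNDS = (3.0, 28.0)  # Angstrom, spans typical FDQ supports
DEFAULT_C_BOUNDS = (1e3, 1e7)


class ConstraintExhaustionError(RuntimeError):
    """All bootstrap solutions violated the C-C bond constraint."""

    def __init__(self, message: str, retained_fraction: float):
        super().__init__(message)
        self.retained_fraction = retained_fraction


@dataclass
class QuenchingDataset:
    """Per-fluorophore replicate dF/G observations."""

    replicates: Mapping[str, np.ndarray]  # fluorophore_tag -> replicate values
    labeled_site_tag: str = ""
    quencher_site_tag: str = ""

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("dataset needs at least one fluorophore")
        clean = {}
        for tag, values in self.replicates.items():
            arr = np.atleast_1d(np.asarray(values, dtype=float))
            if arr.size < 1:
                raise ValueError(f"fluorophore {tag!r} has no replicates")
            clean[tag] = arr
        self.replicates = clean

    @property
    def fluorophores(self) -> list[str]:
        return list(self.replicates.keys())

    def means(self) -> np.ndarray:
        return np.array([self.replicates[t].mean() for t in self.fluorophores])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "QuenchingDataset":
        """Build from a tidy frame with columns fluorophore_tag, deltaF_over_G."""
        required = {"fluorophore_tag", "deltaF_over_G"}
        if not required.issubset(df.columns):
            raise ValueError(f"dataframe must have columns {sorted(required)}")
        groups = {
            str(tag): g["deltaF_over_G"].to_numpy(dtype=float)
            for tag, g in df.groupby("fluorophore_tag", sort=False)
        }
        return cls(replicates=groups, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "QuenchingDataset":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"fluorophore_tag": tag, "replicate_id": i, "deltaF_over_G": v}
            for tag, vals in self.replicates.items()
            for i, v in enumerate(vals)
        ]
        return pd.DataFrame(rows)


@dataclass
class SeedGrid:
    """Cartesian grid of initial guesses, k increments per free parameter."""

    param_names: Sequence[str]
    param_values: Sequence[np.ndarray]

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.param_values]))

    def points(self) -> np.ndarray:
        """All seed combinations, shape (size, n_params)."""
        return np.array(list(itertools.product(*self.param_values)))


def build_seed_grid(
    param_bounds: Mapping[str, tuple[float, float]],
    increments: int = 5,
    log_params: Sequence[str] = ("c",),
) -> SeedGrid:
    """Evenly spaced seeds per parameter, endpoints included; log-spaced for c."""
    names, values = [], []
    for name, (lo, hi) in param_bounds.items():
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
            raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")
        if name in log_params:
            if lo <= 0:
                raise ValueError(f"log-spaced parameter {name!r} needs positive bounds")
            vals = np.geomspace(lo, hi, increments)
        else:
            vals = np.linspace(lo, hi, increments)
        names.append(name)
        values.append(vals)
    return SeedGrid(param_names=names, param_values=values)


def forward_deltaF(fdq: FDQModel, d_r: float, d_a: float, c: float) -> float:
    """dF/G predicted for one fluorophore: c * [FDQ(d_R) - FDQ(d_A)]."""
    if c <= 0:
        raise ValueError("coefficient c must be positive")
    return c * (fdq(d_r) - fdq(d_a))


def bootstrap_resample(
    dataset: QuenchingDataset, n_sets: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Per-fluorophore bootstrap means, shape (n_sets, n_fluorophores).

    For each sample set, every fluorophore's replicates are independently
    resampled with replacement (same size) and averaged.
    """
    rng = np.random.default_rng(seed)
    tags = dataset.fluorophores
    out = np.empty((n_sets, len(tags)))
    for j, tag in enumerate(tags):
        vals = dataset.replicates[tag]
        idx = rng.integers(0, len(vals), size=(n_sets, len(vals)))
        out[:, j] = vals[idx].mean(axis=1)
    return out


def _resolve_fdq_set(fdq_set, tags: Sequence[str]) -> list[FDQModel]:
    """Order FDQ models to match the dataset's fluorophore tags."""
    if isinstance(fdq_set, Mapping):
        by_tag = dict(fdq_set)
    else:
        by_tag = {m.fluorophore_tag: m for m in fdq_set}
    missing = [t for t in tags if t not in by_tag]
    if missing:
        raise ValueError(f"no FDQ model for fluorophore(s) {missing}")
    return [by_tag[t] for t in tags]


def batched_lm(
    residual,
    jac,
    seeds: np.ndarray,
    lo,
    hi,
    max_iter: int = 120,
    ftol: float = 1e-12,
    lam0: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Bounds-projected Levenberg-Marquardt over a whole seed batch at once.

    ``residual(X)`` maps parameter matrix X (n_seeds, n_params) to residuals
    (n_seeds, n_obs); ``jac(X)`` to (n_seeds, n_obs, n_params). Every seed is
    optimised independently (per-seed damping, accept/reject) but in lock-step
    vectorised numpy, which is what makes running 125 seeds per bootstrap set
    affordable. Steps are projected onto the parameter box [lo, hi].

    Returns (X_final, sse_final) for all seeds.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    X = np.clip(np.asarray(seeds, dtype=float), lo, hi)
    n_seeds, n_params = X.shape
    F = residual(X)
    sse = np.einsum("sn,sn->s", F, F)
    lam = np.full(n_seeds, lam0)
    eye = np.eye(n_params)
    stalled = np.zeros(n_seeds, dtype=bool)
    for _ in range(max_iter):
        J = jac(X)
        JT = J.transpose(0, 2, 1)
        A = JT @ J
        g = np.einsum("spn,sn->sp", JT, F)
        diag = np.einsum("spp->sp", A)
        damp = np.maximum(diag, 1e-12)
        M = A + lam[:, None, None] * (damp[:, :, None] * eye[None])
        try:
            delta = -np.linalg.solve(M, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            M = M + 1e-9 * eye[None]
            delta = -np.linalg.solve(M, g[..., None])[..., 0]
        Xn = np.clip(X + delta, lo, hi)
        Fn = residual(Xn)
        ssen = np.einsum("sn,sn->s", Fn, Fn)
        better = ssen < sse
        improved = better & (sse - ssen > ftol * (sse + 1e-300))
        X[better] = Xn[better]
        F[better] = Fn[better]
        sse[better] = ssen[better]
        lam = np.where(better, lam / 3.0, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e12)
        stalled |= (~improved) & (lam >= 1e10)
        if stalled.all():
            break
    return X, sse


def _best_of_seeds(residual, jac, seeds, lo, hi):
    X, sse = batched_lm(residual, jac, seeds, lo, hi)
    j = int(np.argmin(sse))
    return X[j], float(sse[j])


def fit_single_pair(
    sample: np.ndarray,
    fdq_aa: Sequence[FDQModel],
    grid: SeedGrid,
    distance_bounds: tuple[float, float] = DEFAULT_DISTANCE_BOUNDS,
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
) -> tuple[float, float, float, float]:
    """Best-of-seeds 3-parameter fit (d_R, d_A, c) to one bootstrap sample.

    c is optimised on a log scale, which enforces positivity. Returns
    (d_r, d_a, c, sse).
    """
    y = np.asarray(sample, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 fluorophores for a 3-parameter fit")
    models = list(fdq_aa)
    lo = np.array([distance_bounds[0], distance_bounds[0], math.log(c_bounds[0])])
    hi = np.array([distance_bounds[1], distance_bounds[1], math.log(c_bounds[1])])

    def residual(X):
        c = np.exp(X[:, 2])
        vals = np.stack([m(X[:, 0]) - m(X[:, 1]) for m in models], axis=1)
        return c[:, None] * vals - y[None, :]

    def jac(X):
        c = np.exp(X[:, 2])
        J = np.empty((X.shape[0], len(models), 3))
        for i, m in enumerate(models):
            J[:, i, 0] = c * m.derivative(X[:, 0])
            J[:, i, 1] = -c * m.derivative(X[:, 1])
            J[:, i, 2] = c * (m(X[:, 0]) - m(X[:, 1]))
        return J

    pts = grid.points()
    seeds = np.column_stack([pts[:, 0], pts[:, 1], np.log(pts[:, 2])])
    best_x, best_sse = _best_of_seeds(residual, jac, seeds, lo, hi)
    d_r, d_a, log_c = best_x
    return float(d_r), float(d_a), float(math.exp(log_c)), best_sse


def fit_dual_pair(
    sample: np.ndarray,
    fdq_aa: Sequence[FDQModel],
    fdq_ab: Sequence[FDQModel],
    grid: SeedGrid,
    distance_bounds: tuple[float, float] = DEFAULT_DISTANCE_BOUNDS,
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
) -> tuple[float, float, float, float, float, float]:
    """Best-of-seeds 5-parameter fit (d_aa_R, d_aa_A, d_ab_R, d_ab_A, c).

    Both equation systems share c; the residual stacks the alpha-alpha and
    alpha-beta predictions against the same dF/G sample. Returns
    (d_aa_r, d_aa_a, d_ab_r, d_ab_a, c, sse). The C-C bond constraint is
    applied by the caller (solutions are excluded, never projected).
    """
    y = np.asarray(sample, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 fluorophores")
    maa, mab = list(fdq_aa), list(fdq_ab)
    n = len(maa)
    lo = np.array([distance_bounds[0]] * 4 + [math.log(c_bounds[0])])
    hi = np.array([distance_bounds[1]] * 4 + [math.log(c_bounds[1])])

    def residual(X):
        c = np.exp(X[:, 4])
        v_aa = np.stack([m(X[:, 0]) - m(X[:, 1]) for m in maa], axis=1)
        v_ab = np.stack([m(X[:, 2]) - m(X[:, 3]) for m in mab], axis=1)
        return np.concatenate([c[:, None] * v_aa - y, c[:, None] * v_ab - y], axis=1)

    def jac(X):
        c = np.exp(X[:, 4])
        J = np.zeros((X.shape[0], 2 * n, 5))
        for i, m in enumerate(maa):
            J[:, i, 0] = c * m.derivative(X[:, 0])
            J[:, i, 1] = -c * m.derivative(X[:, 1])
            J[:, i, 4] = c * (m(X[:, 0]) - m(X[:, 1]))
        for i, m in enumerate(mab):
            J[:, n + i, 2] = c * m.derivative(X[:, 2])
            J[:, n + i, 3] = -c * m.derivative(X[:, 3])
            J[:, n + i, 4] = c * (m(X[:, 2]) - m(X[:, 3]))
        return J

    pts = grid.points()
    seeds = np.column_stack(
        [pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3], np.log(pts[:, 4])]
    )
    best_x, best_sse = _best_of_seeds(residual, jac, seeds, lo, hi)
    daar, daaa, dabr, daba, log_c = best_x
    return (
        float(daar),
        float(daaa),
        float(dabr),
        float(daba),
        float(math.exp(log_c)),
        best_sse,
    )


def _percentile_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    alpha = 100.0 * (1.0 - level) / 2.0
    return tuple(np.percentile(values, [alpha, 100.0 - alpha]))


class DepetModel:
    """Multi-fluorophore DEPET distance model.

    Parameters
    ----------
    dataset : QuenchingDataset
        Replicate dF/G observations per fluorophore.
    fdq_aa : mapping or sequence of FDQModel
        C-alpha-C-alpha FDQ function per fluorophore (matched by tag).
    fdq_ab : optional
        C-alpha-C-beta FDQ functions; if given, ``fit`` defaults to the
        five-parameter dual mode with the C-C bond constraint.
    """

    def __init__(
        self,
        dataset: QuenchingDataset,
        fdq_aa,
        fdq_ab=None,
        distance_bounds: tuple[float, float] = DEFAULT_DISTANCE_BOUNDS,
        c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
    ):
        self.dataset = dataset
        self.tags = dataset.fluorophores
        self.fdq_aa = _resolve_fdq_set(fdq_aa, self.tags)
        self.fdq_ab = _resolve_fdq_set(fdq_ab, self.tags) if fdq_ab is not None else None
        self.distance_bounds = distance_bounds
        self.c_bounds = c_bounds

    @classmethod
    def from_csv(cls, dataset_path, fdq_table_path, mode: str = "aa_only", **kwargs):
        from .fdq import load_fdq_table

        dataset = QuenchingDataset.from_csv(dataset_path)
        models = load_fdq_table(fdq_table_path)
        fdq_aa = [m for m in models if m.anchor_pair == "aa"]
        fdq_ab = [m for m in models if m.anchor_pair == "ab"]
        if mode == "aa_only" or not fdq_ab:
            return cls(dataset, fdq_aa, **kwargs)
        return cls(dataset, fdq_aa, fdq_ab, **kwargs)

    def fit(
        self,
        n_bootstrap: int = 10_000,
        seed: int = 0,
        seed_increments: int = 5,
        mode: str | None = None,
    ) -> "DepetResults":
        """Bootstrap + best-of-seeds nonlinear least squares.

        ``mode`` is ``"aa_only"`` (3 free parameters) or ``"aa_ab"`` (5 free
        parameters, requires fdq_ab); defaults to dual mode when alpha-beta
        FDQ functions were supplied.
        """
        if mode is None:
            mode = "aa_ab" if self.fdq_ab is not None else "aa_only"
        if mode == "aa_ab" and self.fdq_ab is None:
            raise ValueError("aa_ab mode requires fdq_ab models")

        d_lo, d_hi = self.distance_bounds
        if mode == "aa_only":
            bounds = {"d_r": (d_lo, d_hi), "d_a": (d_lo, d_hi), "c": self.c_bounds}
        else:
            bounds = {
                "d_aa_r": (d_lo, d_hi),
                "d_aa_a": (d_lo, d_hi),
                "d_ab_r": (d_lo, d_hi),
                "d_ab_a": (d_lo, d_hi),
                "c": self.c_bounds,
            }
        grid = build_seed_grid(bounds, increments=seed_increments)
        samples = bootstrap_resample(self.dataset, n_sets=n_bootstrap, seed=seed)

        rows = []
        retained_mask = np.ones(n_bootstrap, dtype=bool)
        for i in range(n_bootstrap):
            if mode == "aa_only":
                d_r, d_a, c, sse = fit_single_pair(
                    samples[i], self.fdq_aa, grid, self.distance_bounds, self.c_bounds
                )
                rows.append((d_r, d_a, c, sse))
            else:
                daar, daaa, dabr, daba, c, sse = fit_dual_pair(
                    samples[i],
                    self.fdq_aa,
                    self.fdq_ab,
                    grid,
                    self.distance_bounds,
                    self.c_bounds,
                )
                ok = (
                    abs(daar - dabr) <= CC_BOND + 1e-12
                    and abs(daaa - daba) <= CC_BOND + 1e-12
                )
                retained_mask[i] = ok
                rows.append((daar, daaa, dabr, daba, c, sse))

        arr = np.array(rows)
        retained = arr[retained_mask]
        retained_fraction = float(retained_mask.mean())
        if len(retained) == 0:
            raise ConstraintExhaustionError(
                "every bootstrap solution violated the C-C bond constraint",
                retained_fraction=0.0,
            )
        return DepetResults(
            model=self,
            mode=mode,
            solutions=retained,
            n_bootstrap=n_bootstrap,
            retained_fraction=retained_fraction,
            seed=seed,
            grid=grid,
            total_fits=n_bootstrap * grid.size,
        )


@dataclass
class DepetResults:
    """Bootstrap distance solutions with means and 95% percentile CIs."""

    model: DepetModel
    mode: str
    solutions: np.ndarray  # per retained draw: aa_only (d_r, d_a, c, sse); aa_ab 6 cols
    n_bootstrap: int
    retained_fraction: float
    seed: int
    grid: SeedGrid
    total_fits: int
    ci_level: float = 0.95

    @property
    def param_names(self) -> list[str]:
        if self.mode == "aa_only":
            return ["d_aa_r", "d_aa_a", "c"]
        return ["d_aa_r", "d_aa_a", "d_ab_r", "d_ab_a", "c"]

    def distribution(self, name: str) -> np.ndarray:
        try:
            j = self.param_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown parameter {name!r}") from exc
        return self.solutions[:, j]

    @property
    def sse(self) -> np.ndarray:
        return self.solutions[:, -1]

    def mean(self, name: str) -> float:
        return float(self.distribution(name).mean())

    def conf_int(self, name: str) -> tuple[float, float]:
        return _percentile_ci(self.distribution(name), self.ci_level)

    def fitted_deltaF(self) -> pd.DataFrame:
        """Mean fitted dF/G per fluorophore over retained bootstrap draws."""
        c = self.distribution("c")
        d_r = self.distribution("d_aa_r")
        d_a = self.distribution("d_aa_a")
        rows = []
        for tag, m in zip(self.model.tags, self.model.fdq_aa):
            fit_vals = c * (m(d_r) - m(d_a))
            rows.append(
                {
                    "fluorophore_tag": tag,
                    "observed_mean": float(self.model.dataset.replicates[tag].mean()),
                    "fitted_mean": float(fit_vals.mean()),
                }
            )
        return pd.DataFrame(rows)

    def orientation_summary(self, cc: float = CC_BOND) -> dict:
        """Trp side-chain orientation per state, from the law of cosines.

        Requires the dual (alpha-alpha + alpha-beta) mode. Draws that violate
        the triangle inequality are excluded and counted.
        """
        if self.mode != "aa_ab":
            raise ValueError("orientation requires alpha-beta distances (aa_ab mode)")
        out = {}
        for state, k_aa, k_ab in (("resting", "d_aa_r", "d_ab_r"), ("active", "d_aa_a", "d_ab_a")):
            d_aa = self.distribution(k_aa)
            d_ab = self.distribution(k_ab)
            angles = []
            n_excluded = 0
            for daa, dab in zip(d_aa, d_ab):
                try:
                    angles.append(angle_from_distances(daa, dab, cc))
                except ValueError:
                    n_excluded += 1
            angles = np.array(angles)
            mean_angle = float(angles.mean())
            coords = planar_coordinates(float(d_aa.mean()), mean_angle, cc)
            out[state] = {
                "angle_mean": mean_angle,
                "angle_ci": _percentile_ci(angles, self.ci_level),
                "x_ca": coords.x,
                "y_ca": coords.y,
                "n_excluded": n_excluded,
            }
        return out

    def summary(self) -> str:
        lines = [
            "DEPET distance fit",
            "=" * 60,
            f"mode: {self.mode}    fluorophores: {len(self.model.tags)}",
            f"bootstrap sets: {self.n_bootstrap}    seed grid: {self.grid.size} "
            f"({self.total_fits} total fits)",
            f"retained fraction: {self.retained_fraction:.3f}    seed: {self.seed}",
            "-" * 60,
            f"{'parameter':>10} {'mean':>12} {'95% CI low':>12} {'95% CI high':>12}",
        ]
        for name in self.param_names:
            m = self.mean(name)
            lo, hi = self.conf_int(name)
            if name == "c":
                lines.append(f"{name:>10} {m:>12.4g} {lo:>12.4g} {hi:>12.4g}")
            else:
                lines.append(f"{name:>10} {m:>12.3f} {lo:>12.3f} {hi:>12.3f}")
        lines.append("-" * 60)
        lines.append("distances in Angstrom; CI = bootstrap percentile interval")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "total_fits": self.total_fits,
            "retained_fraction": self.retained_fraction,
            "parameters": {},
        }
        for name in self.param_names:
            lo, hi = self.conf_int(name)
            d["parameters"][name] = {
                "mean": self.mean(name),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        return d


def run_depet(
    dataset: QuenchingDataset,
    fdq_aa,
    fdq_ab=None,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    mode: str = "aa_only",
    **model_kwargs,
) -> DepetResults:
    """One-call convenience wrapper around DepetModel(...).fit(...)."""
    model = DepetModel(dataset, fdq_aa, fdq_ab=fdq_ab, **model_kwargs)
    return model.fit(n_bootstrap=n_bootstrap, seed=seed, mode=mode)
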