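"""Peptide length standards.

Rigid Cys-(Pro)n-Trp peptides act as molecular rulers: the C-terminal Trp
quenches an N-terminally conjugated fluorophore according to the FDQ
function at the peptide's fixed Cys-Trp separation. Intramolecular quenching
is measured chromatographically as

    Q = 1 - (F_conj / A_conj) / (F_free / A_free)

(fluorescence per unit absorbance of the conjugate peak relative to the free
dye peak), and Q = c * FDQ_aa(X, d) is fit across fluorophores X to recover
the peptide length d. Comparing the recovered d against the nominal
polyproline-II length (``structure_tools.build_ppii``) quantifies the
accuracy of the whole distance-inference chain.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .distance_fit import (
    DEFAULT_C_BOUNDS,
    DEFAULT_DISTANCE_BOUNDS,
    SeedGrid,
    _best_of_seeds,
    build_seed_grid,
)
from .fdq import FDQModel

__all__ = [
    "PeptideQuenchRecord",
    "PeptideLengthModel",
    "PeptideLengthResults",
    "intramolecular_quenching",
    "fit_peptide_length",
    "peak_table_from_chromatogram",
    "select_conjugate_peak",
]

log = logging.getLogger(__name__)


@dataclass
class PeptideQuenchRecord:
    """HPLC peak quantities for one fluorophore-peptide conjugate run."""

    fluorophore_tag: str
    f_conj: float
    a_conj: float
    f_free: float
    a_free: float

    def __post_init__(self) -> None:
        if self.a_conj <= 0 or self.a_free <= 0:
            raise ValueError("absorbances must be positive")

    @property
    def quenching(self) -> float:
        return intramolecular_quenching(self)


def intramolecular_quenching(record: PeptideQuenchRecord) -> float:
    """Q = 1 - (F_conj/A_conj)/(F_free/A_free), clamped to [0, 1].

    A negative raw value (conjugate apparently brighter than free dye, which
    noise can produce) clamps to 0 with a warning.
    """
    q = 1.0 - (record.f_conj / record.a_conj) / (record.f_free / record.a_free)
    if q < 0:
        warnings.warn(
            f"negative quenching ({q:.3g}) for {record.fluorophore_tag}; clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return min(q, 1.0)


def _resolve_fdq(fdq_set, tags):
    if isinstance(fdq_set, Mapping):
        by_tag = dict(fdq_set)
    else:
        by_tag = {m.fluorophore_tag: m for m in fdq_set}
    missing = [t for t in tags if t not in by_tag]
    if missing:
        raise ValueError(f"no FDQ model for fluorophore(s) {missing}")
    return [by_tag[t] for t in tags]


def _fit_quenching(y, models, grid, distance_bounds, c_bounds):
    """Best-of-seeds 2-parameter (d, log c) least squares of Q = c FDQ(d)."""
    lo = np.array([distance_bounds[0], math.log(c_bounds[0])])
    hi = np.array([distance_bounds[1], math.log(c_bounds[1])])

    def residual(X):
        c = np.exp(X[:, 1])
        vals = np.stack([m(X[:, 0]) for m in models], axis=1)
        return c[:, None] * vals - y[None, :]

    def jac(X):
        c = np.exp(X[:, 1])
        J = np.empty((X.shape[0], len(models), 2))
        for i, m in enumerate(models):
            J[:, i, 0] = c * m.derivative(X[:, 0])
            J[:, i, 1] = c * m(X[:, 0])
        return J

    pts = grid.points()
    seeds = np.column_stack([pts[:, 0], np.log(pts[:, 1])])
    best_x, best_sse = _best_of_seeds(residual, jac, seeds, lo, hi)
    d, log_c = best_x
    return float(d), float(math.exp(log_c)), best_sse


class PeptideLengthModel:
    """Fit a peptide's Cys-Trp C-alpha distance from per-fluorophore quenching.

    ``records`` is a sequence of PeptideQuenchRecord (replicates allowed per
    fluorophore); quenching replicates of a fluorophore are bootstrap-resampled
    for the confidence interval.
    """

    def __init__(
        self,
        records: Sequence[PeptideQuenchRecord],
        fdq_aa,
        distance_bounds=DEFAULT_DISTANCE_BOUNDS,
        c_bounds=DEFAULT_C_BOUNDS,
    ):
        if not records:
            raise ValueError("need at least one quench record")
        self.quenching: dict[str, list[float]] = {}
        for rec in records:
            self.quenching.setdefault(rec.fluorophore_tag, []).append(rec.quenching)
        self.tags = list(self.quenching.keys())
        if len(self.tags) < 2:
            raise ValueError("need >= 2 fluorophores to constrain (d, c)")
        if all(all(v == 0 for v in vals) for vals in self.quenching.values()):
            raise ValueError("all-zero quenching across fluorophores: d is unidentifiable")
        self.fdq_aa = _resolve_fdq(fdq_aa, self.tags)
        self.distance_bounds = distance_bounds
        self.c_bounds = c_bounds

    def fit(
        self,
        seed_increments: int = 5,
        n_bootstrap: int = 0,
        seed: int = 0,
    ) -> "PeptideLengthResults":
        grid = build_seed_grid(
            {"d": self.distance_bounds, "c": self.c_bounds}, increments=seed_increments
        )
        y = np.array([np.mean(self.quenching[t]) for t in self.tags])
        d, c, sse = _fit_quenching(y, self.fdq_aa, grid, self.distance_bounds, self.c_bounds)

        d_boot = c_boot = None
        if n_bootstrap:
            rng = np.random.default_rng(seed)
            d_list, c_list = [], []
            reps = {t: np.asarray(self.quenching[t]) for t in self.tags}
            for _ in range(n_bootstrap):
                yb = np.array(
                    [reps[t][rng.integers(0, len(reps[t]), len(reps[t]))].mean() for t in self.tags]
                )
                db, cb, _ = _fit_quenching(yb, self.fdq_aa, grid, self.distance_bounds, self.c_bounds)
                d_list.append(db)
                c_list.append(cb)
            d_boot, c_boot = np.array(d_list), np.array(c_list)
        return PeptideLengthResults(
            model=self, d_aa=d, c=c, sse=sse, d_bootstrap=d_boot, c_bootstrap=c_boot
        )


@dataclass
class PeptideLengthResults:
    model: PeptideLengthModel
    d_aa: float
    c: float
    sse: float
    d_bootstrap: np.ndarray | None = None
    c_bootstrap: np.ndarray | None = None
    ci_level: float = 0.95

    def conf_int(self) -> tuple[float, float] | None:
        if self.d_bootstrap is None:
            return None
        alpha = 100.0 * (1.0 - self.ci_level) / 2.0
        lo, hi = np.percentile(self.d_bootstrap, [alpha, 100.0 - alpha])
        return float(lo), float(hi)

    def fitted_quenching(self) -> pd.DataFrame:
        rows = []
        for tag, m in zip(self.model.tags, self.model.fdq_aa):
            rows.append(
                {
                    "fluorophore_tag": tag,
                    "observed": float(np.mean(self.model.quenching[tag])),
                    "fitted": self.c * m(self.d_aa),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Peptide length fit",
            "=" * 48,
            f"fluorophores: {len(self.model.tags)}",
            f"d_aa = {self.d_aa:.2f} Angstrom",
        ]
        ci = self.conf_int()
        if ci:
            lines.append(f"95% CI [{ci[0]:.2f}, {ci[1]:.2f}] Angstrom")
        lines.append(f"c = {self.c:.4g}    SSE = {self.sse:.3g}")
        return "\n".join(lines)


def fit_peptide_length(
    records: Sequence[PeptideQuenchRecord],
    fdq_aa,
    seed_increments: int = 5,
    n_bootstrap: int = 0,
    seed: int = 0,
    **model_kwargs,
) -> PeptideLengthResults:
    """One-call wrapper around PeptideLengthModel(...).fit(...)."""
    return PeptideLengthModel(records, fdq_aa, **model_kwargs).fit(
        seed_increments=seed_increments, n_bootstrap=n_bootstrap, seed=seed
    )


def peak_table_from_chromatogram(
    time,
    absorbance_550,
    fluorescence_575,
    height_fraction: float = 0.05,
    reference_times: Sequence[float] = (),
    match_tolerance: float = 0.5,
) -> pd.DataFrame:
    """Detect elution peaks and integrate their areas.

    A peak is a local maximum of absorbance above ``height_fraction`` of the
    trace maximum; its bounds are the surrounding valleys and areas are
    trapezoidal. ``reference_times`` (retention times from a dye-only run)
    assign species: a peak within ``match_tolerance`` minutes of a reference
    time is labelled "free", any other peak "conjugate".
    """
    t = np.asarray(time, dtype=float)
    a = np.asarray(absorbance_550, dtype=float)
    f = np.asarray(fluorescence_575, dtype=float)
    if not (len(t) == len(a) == len(f)):
        raise ValueError("trace arrays must have equal length")
    if len(t) > 1 and not np.allclose(np.diff(t), t[1] - t[0], rtol=1e-6):
        raise ValueError("trace must be uniformly sampled")

    if a.max() <= 0:
        log.warning("flat chromatogram: no peaks")
        return pd.DataFrame(
            columns=["retention_time", "height", "absorbance_area", "fluorescence_area", "species"]
        )
    threshold = height_fraction * a.max()
    peaks, _ = find_peaks(a, height=threshold)
    if len(peaks) == 0:
        log.warning("no peaks above threshold %.3g", threshold)
        return pd.DataFrame(
            columns=["retention_time", "height", "absorbance_area", "fluorescence_area", "species"]
        )

    rows = []
    for p in peaks:
        # valley bounds: walk down until the trace stops decreasing or hits the ends
        left = p
        while left > 0 and a[left - 1] < a[left]:
            left -= 1
        right = p
        while right < len(a) - 1 and a[right + 1] < a[right]:
            right += 1
        sl = slice(left, right + 1)
        rt = float(t[p])
        species = "conjugate"
        for ref in reference_times:
            if abs(rt - ref) <= match_tolerance:
                species = "free"
                break
        rows.append(
            {
                "retention_time": rt,
                "height": float(a[p]),
                "absorbance_area": float(np.trapezoid(a[sl], t[sl])),
                "fluorescence_area": float(np.trapezoid(f[sl], t[sl])),
                "species": species,
            }
        )
    return pd.DataFrame(rows)


def select_conjugate_peak(table: pd.DataFrame) -> pd.Series:
    """The most abundant conjugate species of a run: largest conjugate
    absorbance area. That peak's quantities feed the length fit."""
    conj = table[table["species"] == "conjugate"]
    if conj.empty:
        raise ValueError("no conjugate peaks in table")
    return conj.loc[conj["absorbance_area"].idxmax()]
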