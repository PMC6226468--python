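"""Synthetic generators for every experimental input the toolkit consumes.

The real inputs are molecular-dynamics conformer ensembles, voltage-clamp
fluorometry sweeps, dF/G replicate tables, Stern-Volmer titrations and HPLC
peak tables. Each generator here forward-simulates one of them from known
ground truth so every inverse pipeline can be exercised end-to-end without
external data. All generators are pure functions of (spec, seed).

The conformer sampler is a freely-rotating chain with Gaussian bend noise,
a deliberate simplification of the 100-ps MD runs it stands in for: it only
needs to reproduce the qualitative family behaviour (a longer linker gives a
broader, longer-reaching fluorophore density), not force-field physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conformer_density import ConformerEnsemble
from .distance_fit import QuenchingDataset, forward_deltaF
from .fdq import FDQModel
from .peptide_standards import PeptideQuenchRecord
from .signal_processing import SweepRecord, _boltzmann, DEFAULT_TEMPERATURE

__all__ = [
    "ChainSamplerSpec",
    "synth_conformer_cloud",
    "synth_quenching_dataset",
    "synth_sweep",
    "synth_titration",
    "synth_peptide_peaks",
    "example_fdq_family",
    "DEFAULT_VOLTAGE_PROTOCOL",
]

#: Test-pulse protocol: -220 to +160 mV in 20 mV increments (20 potentials).
DEFAULT_VOLTAGE_PROTOCOL = np.arange(-220.0, 160.0 + 1e-9, 20.0)

#: Quencher concentration series for Stern-Volmer titrations (M).
DEFAULT_TITRATION_CONCENTRATIONS = np.array([0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0]) * 1e-6


@dataclass
class ChainSamplerSpec:
    """Freely-rotating-chain sampler for a dye linker.

    ``n_bonds`` chain bonds of ``bond_length`` Angstrom; successive bond
    directions bend by Gaussian angles (degrees); the moiety centroid sits
    ``moiety_offset`` Angstrom beyond the chain end along the last bond.
    """

    n_bonds: int
    bond_length: float = 1.5
    bend_angle_mean: float = 60.0
    bend_angle_sd: float = 15.0
    moiety_offset: float = 2.0
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.bond_length <= 0 or self.moiety_offset < 0:
            raise ValueError("lengths must be positive")
        if self.n_bonds < 1:
            raise ValueError("need at least one bond")


def _random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def synth_conformer_cloud(spec: ChainSamplerSpec) -> ConformerEnsemble:
    """Sample chain conformers; anchor at the origin, moiety at the chain end."""
    rng = np.random.default_rng(spec.seed)
    n, nb = spec.n_frames, spec.n_bonds
    positions = np.zeros((n, nb + 2, 3))  # nodes 0..nb, then the moiety centroid

    directions = _random_unit_vectors(rng, n)
    current = directions * spec.bond_length
    positions[:, 1] = current
    prev_dir = directions
    for b in range(1, nb):
        bend = np.radians(rng.normal(spec.bend_angle_mean, spec.bend_angle_sd, size=n))
        azimuth = rng.uniform(0.0, 2.0 * math.pi, size=n)
        # orthonormal frame around the previous bond direction
        helper = np.where(
            np.abs(prev_dir[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
        )
        e1 = np.cross(prev_dir, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(prev_dir, e1)
        new_dir = (
            np.cos(bend)[:, None] * prev_dir
            + np.sin(bend)[:, None] * (np.cos(azimuth)[:, None] * e1 + np.sin(azimuth)[:, None] * e2)
        )
        new_dir /= np.linalg.norm(new_dir, axis=1, keepdims=True)
        positions[:, b + 1] = positions[:, b] + new_dir * spec.bond_length
        prev_dir = new_dir
    positions[:, nb + 1] = positions[:, nb] + prev_dir * spec.moiety_offset

    labels = ["ANC"] + [f"C{i}" for i in range(1, nb + 1)] + ["MOI"]
    return ConformerEnsemble(
        frames=positions,
        atom_labels=labels,
        anchor_index=0,
        moiety_indices=[nb + 1],
        source_tag=f"chain{nb}",
    )


def synth_quenching_dataset(
    fdq_set,
    d_r: float,
    d_a: float,
    c: float,
    noise_cv: float = 0.1,
    n_replicates: int = 5,
    seed: int = 0,
) -> QuenchingDataset:
    """Forward-model dF/G replicates from known distances and coefficient c.

    Per fluorophore, replicates are forward_deltaF x (1 + cv * N(0,1)).
    """
    if c <= 0:
        raise ValueError("c must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    models = list(fdq_set.values()) if hasattr(fdq_set, "values") else list(fdq_set)
    replicates = {}
    for m in models:
        truth = forward_deltaF(m, d_r, d_a, c)
        noise = rng.normal(0.0, noise_cv, size=n_replicates) if noise_cv else np.zeros(n_replicates)
        replicates[m.fluorophore_tag] = truth * (1.0 + noise)
    return QuenchingDataset(replicates=replicates)


def synth_sweep(
    delta_f_total: float = 5.0,
    v_half: float = -20.0,
    z: float = 1.3,
    delta_f_min: float = 0.0,
    bleach_amplitude: float = 0.0,
    bleach_tau: float = 200.0,
    noise_sd: float = 0.0,
    protocol=None,
    baseline_f: float = 100.0,
    g_max: float = 10.0,
    e_k: float = -90.0,
    pulse_start_ms: float = 20.0,
    pulse_end_ms: float = 70.0,
    total_ms: float = 100.0,
    dt_ms: float = 0.5,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
):
    """Simulate a family of voltage-clamp fluorometry sweeps.

    Returns (sweeps, reference) where ``sweeps`` is one SweepRecord per test
    potential of the protocol (default -220..+160 mV in 20 mV steps) and
    ``reference`` is a matching no-pulse recording carrying only the bleach
    and noise, for bleach correction.
    """
    if protocol is None:
        protocol = DEFAULT_VOLTAGE_PROTOCOL
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_ms, dt_ms)
    in_pulse = (t >= pulse_start_ms) & (t < pulse_end_ms)
    bleach = bleach_amplitude * np.exp(-t / bleach_tau)

    sweeps = []
    for v in protocol:
        df = _boltzmann(np.array([v]), delta_f_total, v_half, z, delta_f_min, temperature)[0]
        f = baseline_f + bleach + np.where(in_pulse, df, 0.0)
        if noise_sd:
            f = f + rng.normal(0.0, noise_sd, size=t.shape)
        g = _boltzmann(np.array([v]), g_max, v_half, z, 0.0, temperature)[0]
        # conductance in uS so current comes out in nA for mV driving force
        i = np.where(in_pulse, g * (v - e_k), 0.0) * np.ones_like(t)
        voltage = np.where(in_pulse, v, -90.0)
        sweeps.append(
            SweepRecord(
                time=t, fluorescence=f, current=i, voltage=voltage,
                e_k=e_k, temperature=temperature,
            )
        )
    f_ref = baseline_f + bleach
    if noise_sd:
        f_ref = f_ref + rng.normal(0.0, noise_sd, size=t.shape)
    reference = SweepRecord(
        time=t,
        fluorescence=f_ref,
        current=np.zeros_like(t),
        voltage=np.full_like(t, -90.0),
        e_k=e_k,
        temperature=temperature,
    )
    return sweeps, reference


def synth_titration(
    ksv: float = 40.0,
    concentrations=None,
    noise_cv: float = 0.0,
    f0: float = 1000.0,
    seed: int = 0,
):
    """Simulate a Stern-Volmer titration: returns (conc, fluorescence, absorbance).

    Absorbances vary between wells (pipetting spread) to exercise the
    normalisation; fluorescence follows F = A * f0 / (1 + ksv [Q]).

    ``noise_cv`` is the relative error on the measured quenching increment
    ksv [Q] itself, not on the raw fluorescence: at micromolar quencher and
    K_SV of order 10 M^-1 the increment is ~1e-3 of F, so noise is only
    meaningful on the scale of the quantity the titration actually resolves
    (the ratioed, baseline-referenced quenching signal).
    """
    if concentrations is None:
        concentrations = DEFAULT_TITRATION_CONCENTRATIONS
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    absorbance = 0.5 * (1.0 + 0.05 * rng.standard_normal(len(c)))
    quench = ksv * c
    if noise_cv:
        quench = quench * (1.0 + noise_cv * rng.standard_normal(len(c)))
    f = absorbance * f0 / (1.0 + quench)
    return c, f, absorbance


def synth_peptide_peaks(
    fdq_set,
    d: float,
    c: float,
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[PeptideQuenchRecord]:
    """Forward-model HPLC peak quantities for a peptide of known length d.

    Quenching Q = c * FDQ(d) sets the conjugate's fluorescence-per-absorbance
    relative to the free dye; replicate records get multiplicative noise on
    the conjugate fluorescence.
    """
    rng = np.random.default_rng(seed)
    models = list(fdq_set.values()) if hasattr(fdq_set, "values") else list(fdq_set)
    records = []
    for m in models:
        q = c * m(d)
        for _ in range(n_replicates):
            noisy_q = q * (1.0 + noise_cv * rng.standard_normal()) if noise_cv else q
            noisy_q = min(max(noisy_q, 0.0), 1.0)
            records.append(
                PeptideQuenchRecord(
                    fluorophore_tag=m.fluorophore_tag,
                    f_conj=(1.0 - noisy_q) * 80.0,
                    a_conj=80.0,
                    f_free=100.0,
                    a_free=100.0,
                )
            )
    return records


def example_fdq_family(n: int = 6, anchor_pair: str = "aa") -> list[FDQModel]:
    """A fixed six-member FDQ family emulating dye linkers of increasing length.

    Single-Gaussian quenching profiles whose means march outward (about 8 to
    20 Angstrom, spanning the ~6-25 Angstrom working range of the method)
    and broaden with linker length, peaking near 2e-5 — realistic magnitudes
    for the doubly-volume-normalised contact probabilities the pipeline
    produces. The alpha-beta variant is shifted 1 Angstrom inward (the
    C-beta anchor sits one bond closer to the ring).
    """
    if not 2 <= n <= 6:
        raise ValueError("family supports 2..6 members")
    means = np.array([8.0, 10.0, 12.0, 14.5, 17.0, 20.0])[:n]
    sds = np.array([1.8, 2.0, 2.2, 2.5, 2.8, 3.2])[:n]
    peak = 2e-5
    if anchor_pair == "ab":
        means = means - 1.0
    models = []
    for k, (mu, sd) in enumerate(zip(means, sds)):
        A = peak * math.sqrt(2.0 * math.pi * sd)
        models.append(
            FDQModel(
                gauss_amplitudes=[A],
                gauss_means=[mu],
                gauss_sds=[sd],
                fluorophore_tag=f"TMR-L{k + 1}",
                anchor_pair=anchor_pair,
            )
        )
    return models
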