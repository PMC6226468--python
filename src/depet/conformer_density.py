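"""Radial probability densities of moiety centroids about anchor atoms.

A conformer ensemble of a dye-residue conjugate (or of tryptophan alone)
is reduced to a one-dimensional histogram: the probability of finding the
centroid of the fluorescent (xanthene) or quenching (indole) ring system at
a given radius from an anchor atom (C-alpha or C-beta). These densities are
the ``f`` and ``q`` inputs from which quenching-probability curves are built.

Conventions: bin k covers the half-open radial interval ((k-1)*dr, k*dr],
with dr = 0.05 Angstrom by default, and each bin holds probability mass
(counts divided by the total number of frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ConformerEnsemble",
    "RadialDensity",
    "moiety_centroid",
    "radial_histogram",
    "ensemble_to_density",
    "read_ensemble",
]

DEFAULT_BIN_WIDTH = 0.05  # Angstrom


@dataclass
class ConformerEnsemble:
    """Coordinate snapshots of a dye-residue conjugate.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom. ``anchor_index``
    names the C-alpha (or C-beta) atom; ``moiety_indices`` the atoms of the
    fluorescent or quenching ring system.
    """

    frames: np.ndarray
    atom_labels: Sequence[str]
    anchor_index: int
    moiety_indices: Sequence[int]
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if len(self.atom_labels) != self.frames.shape[1]:
            raise ValueError("atom_labels length must match atom count")
        if self.anchor_index in set(self.moiety_indices):
            raise ValueError("anchor atom cannot be part of the moiety")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class RadialDensity:
    """Binned probability of a moiety centroid at a given radius from an anchor."""

    bin_width: float
    probabilities: np.ndarray  # bin k (1-based) covers ((k-1)*dr, k*dr]
    anchor_kind: str = "Ca"  # "Ca" or "Cb"
    moiety_kind: str = "xanthene"  # "xanthene" or "indole"
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.probabilities.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")

    @property
    def bin_max_radii(self) -> np.ndarray:
        """Maximal radius of each bin (the shell's outer radius)."""
        return self.bin_width * np.arange(1, len(self.probabilities) + 1)

    @property
    def support_radius(self) -> float:
        """Outer radius of the last occupied bin."""
        occ = np.nonzero(self.probabilities)[0]
        if len(occ) == 0:
            return 0.0
        return float((occ[-1] + 1) * self.bin_width)

    def mean(self) -> float:
        """Mean radius using bin centers."""
        centers = self.bin_max_radii - 0.5 * self.bin_width
        return float(np.sum(centers * self.probabilities))


def moiety_centroid(frame: np.ndarray, moiety_indices: Sequence[int]) -> np.ndarray:
    """Unweighted centroid of the selected atoms in one frame."""
    idx = np.asarray(moiety_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("moiety_indices must not be empty")
    return np.asarray(frame, dtype=float)[idx].mean(axis=0)


def radial_histogram(
    distances: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH
) -> RadialDensity:
    """Bin anchor-centroid distances into a probability-mass histogram.

    A distance exactly on a bin edge is assigned to the lower-indexed covering
    bin (half-open bins ((k-1)*dr, k*dr]).
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one distance")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # bin index k (1-based) with d in ((k-1)dr, k dr]; ceil with edge-to-lower
    k = np.ceil(d / bin_width).astype(int)
    k[k < 1] = 1  # d == 0 goes into the innermost bin
    n_bins = int(k.max())
    counts = np.bincount(k - 1, minlength=n_bins).astype(float)
    return RadialDensity(
        bin_width=bin_width,
        probabilities=counts / d.size,
        n_samples=int(d.size),
    )


def ensemble_to_density(
    ensemble: ConformerEnsemble,
    bin_width: float = DEFAULT_BIN_WIDTH,
    anchor_kind: str = "Ca",
    moiety_kind: str = "xanthene",
) -> RadialDensity:
    """Histogram of anchor-to-moiety-centroid distances over all frames."""
    idx = np.asarray(ensemble.moiety_indices, dtype=int)
    centroids = ensemble.frames[:, idx, :].mean(axis=1)
    anchors = ensemble.frames[:, ensemble.anchor_index, :]
    distances = np.linalg.norm(centroids - anchors, axis=1)
    density = radial_histogram(distances, bin_width=bin_width)
    density.anchor_kind = anchor_kind
    density.moiety_kind = moiety_kind
    return density


def _read_xyz_frames(path: Path) -> tuple[np.ndarray, list[str]]:
    """Parse a concatenated-XYZ trajectory (n_atoms / comment / atom lines)."""
    frames: list[np.ndarray] = []
    labels: list[str] | None = None
    lines = path.read_text().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"malformed XYZ header at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValueError(f"truncated XYZ frame {frame_no}")
        frame_labels = []
        coords = np.empty((n_atoms, 3))
        for j, line in enumerate(block):
            parts = line.split()
            frame_labels.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        if labels is None:
            labels = frame_labels
        elif len(frame_labels) != len(labels):
            raise ValueError(f"inconsistent atom count in XYZ frame {frame_no}")
        frames.append(coords)
        i += 2 + n_atoms
        frame_no += 1
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return np.stack(frames), labels


def _read_pdb_frames(path: Path) -> tuple[np.ndarray, list[str]]:
    """Read a multi-model PDB trajectory via Biopython."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ensemble", str(path))
    frames: list[np.ndarray] = []
    labels: list[str] | None = None
    for m_idx, model in enumerate(structure):
        atoms = [
            a
            for a in model.get_atoms()
            if a.get_altloc() in (" ", "A")
        ]
        frame_labels = [a.get_name() for a in atoms]
        if labels is None:
            labels = frame_labels
        elif len(frame_labels) != len(labels):
            raise ValueError(f"inconsistent atom count in PDB MODEL {m_idx + 1}")
        frames.append(np.array([a.get_coord() for a in atoms], dtype=float))
    if not frames:
        raise ValueError(f"no models found in {path}")
    return np.stack(frames), labels


def read_ensemble(
    path,
    format: str | None = None,
    anchor_selector: str = "CA",
    moiety_selector: Sequence[str] = (),
    source_tag: str = "",
) -> ConformerEnsemble:
    """Load a conformer ensemble from a multi-model PDB or XYZ trajectory.

    ``anchor_selector`` is a single atom name; ``moiety_selector`` a list of
    atom names whose union forms the moiety. Selectors must resolve to the
    same atoms in every frame (guaranteed by the per-frame atom-count check).
    """
    path = Path(path)
    fmt = format or ("xyz" if path.suffix.lower() == ".xyz" else "pdb")
    if fmt == "xyz":
        frames, labels = _read_xyz_frames(path)
    elif fmt == "pdb":
        frames, labels = _read_pdb_frames(path)
    else:
        raise ValueError(f"unknown ensemble format {fmt!r}")

    anchor_matches = [i for i, lab in enumerate(labels) if lab == anchor_selector]
    if len(anchor_matches) != 1:
        raise ValueError(
            f"anchor selector {anchor_selector!r} matched {len(anchor_matches)} atoms"
        )
    wanted = set(moiety_selector)
    moiety_indices = [i for i, lab in enumerate(labels) if lab in wanted]
    if not moiety_indices:
        raise ValueError(f"moiety selector {sorted(wanted)} matched no atoms")
    return ConformerEnsemble(
        frames=frames,
        atom_labels=labels,
        anchor_index=anchor_matches[0],
        moiety_indices=moiety_indices,
        source_tag=source_tag or path.stem,
    )
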