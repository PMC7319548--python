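"""Seeded generator of synthetic chemical-shift datasets.

Emulates BMRB-style assignment tables well enough to train, calibrate and
evaluate the compression pipeline offline: each protein gets a random
sequence, a secondary-structure path from a three-state Markov chain
(H helix / E sheet / C coil), and per-atom shifts drawn as

    shift = coil reference mean(residue type, atom)
            + structure offset(atom class)  + Gaussian noise.

The coil reference means and the helix/sheet offsets are SYNTHETIC fixture
constants: their magnitudes are plausible ppm values and the offset signs
follow the canonical secondary-shift directions (CA and C move downfield
in helices and upfield in sheets; CB and HA the opposite), but they are
not literature random-coil tables.  Only the sign structure and the
separability of the three classes matter for what this generator is used
for.

Denatured mode emulates urea unfolding: all-coil structure with inflated
noise, plus an optional residual-structure fraction that lets some
residues keep native-like conformational preferences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .encoding import build_scheme
from .shift_io import (Residue, ShiftTable, STANDARD_RESIDUES,
                       write_nef, write_nmrstar)

STATES = ("H", "E", "C")

_FULL_SCHEME = build_scheme("full")

# Synthetic coil reference baselines per atom class (ppm).
_BASE_MEANS = {
    "H": 8.30, "HA": 4.35, "HA2": 3.95, "HA3": 3.90,
    "CA": 58.0, "CB": 33.0, "C": 176.0, "N": 119.0,
}
_CLASS_BASE = {"H": 1.80, "C": 32.0, "N": 112.0}   # other side-chain atoms
_CLASS_JITTER = {"H": 0.25, "C": 1.5, "N": 3.0}    # per-(type,atom) spread

# A few anchors so familiar residues look right.
_SPECIAL_MEANS = {
    ("GLY", "CA"): 45.4, ("ALA", "CA"): 52.5, ("ALA", "CB"): 19.0,
    ("SER", "CB"): 63.8, ("THR", "CB"): 69.8, ("PRO", "CA"): 63.1,
    ("GLY", "N"): 109.5, ("PRO", "N"): 137.0,
}

# Secondary-shift offsets per atom class (ppm).  Helix: CA/C downfield,
# CB/HA upfield; sheet roughly opposite with larger HA/CB moves.
_HELIX_OFFSET = {"CA": 3.1, "C": 2.2, "CB": -0.5, "HA": -0.35,
                 "H": -0.25, "N": -1.5}
_SHEET_OFFSET = {"CA": -1.8, "C": -1.4, "CB": 2.3, "HA": 0.45,
                 "H": 0.30, "N": 2.5}

_NOISE_STD = {"H": 0.15, "C": 0.8, "N": 1.5}       # per element class


def _atom_class(atom: str) -> str:
    """Backbone offset class of an atom name; '' for plain side-chain atoms."""
    if atom in ("HA", "HA2", "HA3"):
        return "HA"
    if atom in ("H", "CA", "CB", "C", "N"):
        return atom
    return ""


def _element(atom: str) -> str:
    return atom[0]      # H / C / N by nomenclature convention


@dataclass(frozen=True)
class ReferenceShiftTable:
    """Frozen synthetic coil means and secondary-structure offsets."""

    coil_mean: dict[tuple[str, str], float]
    helix_offset: dict[str, float]
    sheet_offset: dict[str, float]

    def mean(self, residue_type: str, atom: str, state: str) -> float:
        mu = self.coil_mean[(residue_type, atom)]
        cls = _atom_class(atom)
        if cls:
            if state == "H":
                mu += self.helix_offset.get(cls, 0.0)
            elif state == "E":
                mu += self.sheet_offset.get(cls, 0.0)
        return mu


def build_reference() -> ReferenceShiftTable:
    """Deterministic synthetic reference table over the full atom scheme."""
    jitter_rng = np.random.default_rng(20200527)    # frozen: part of the table
    coil: dict[tuple[str, str], float] = {}
    for rt in sorted(STANDARD_RESIDUES):
        for atom in _FULL_SCHEME.atoms(rt):
            el = _element(atom)
            base = _BASE_MEANS.get(atom, _CLASS_BASE[el])
            value = base + jitter_rng.normal(0.0, _CLASS_JITTER[el])
            coil[(rt, atom)] = _SPECIAL_MEANS.get((rt, atom), value)
    return ReferenceShiftTable(coil, dict(_HELIX_OFFSET), dict(_SHEET_OFFSET))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``persistence`` is the per-state probability of staying in the same
    secondary-structure state at the next residue (segment lengths are
    geometric with mean 1/(1-p)); ``entry_probs`` weight which state is
    entered at the start and after leaving a segment.
    """

    n_proteins: int = 40
    length_range: tuple[int, int] = (50, 150)
    persistence: dict[str, float] = field(
        default_factory=lambda: {"H": 0.92, "E": 0.88, "C": 0.85})
    entry_probs: dict[str, float] = field(
        default_factory=lambda: {"H": 0.35, "E": 0.25, "C": 0.40})
    noise_std: dict[str, float] = field(default_factory=lambda: dict(_NOISE_STD))
    missing_rate: float = 0.10
    mode: str = "native"
    denatured_noise_factor: float = 1.5
    residual_structure_fraction: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.mode not in ("native", "denatured"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.length_range[0] < 5:
            raise ValueError("minimum protein length is 5")
        for p in (*self.persistence.values(), *self.entry_probs.values(),
                  self.missing_rate, self.residual_structure_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if any(s <= 0 for s in self.noise_std.values()):
            raise ValueError("noise std must be positive")


def _structure_path(length: int, cfg: GeneratorConfig,
                    rng: np.random.Generator) -> str:
    entry = np.array([cfg.entry_probs[s] for s in STATES], dtype=float)
    entry = entry / entry.sum()
    state = STATES[rng.choice(3, p=entry)]
    path = [state]
    for _ in range(length - 1):
        if rng.random() < cfg.persistence[state]:
            path.append(state)
            continue
        others = [s for s in STATES if s != state]
        w = np.array([cfg.entry_probs[s] for s in others], dtype=float)
        state = others[rng.choice(2, p=w / w.sum())]
        path.append(state)
    return "".join(path)


def generate(config: GeneratorConfig,
             reference: ReferenceShiftTable | None = None
             ) -> tuple[list[ShiftTable], list[str]]:
    """Draw a synthetic dataset; fully determined by ``config.seed``.

    Returns the shift tables and, parallel to them, per-residue
    secondary-structure label strings over {H, E, C}.
    """
    ref = reference or build_reference()
    rng = np.random.default_rng(config.seed)
    types = sorted(STANDARD_RESIDUES)
    noise_factor = (config.denatured_noise_factor
                    if config.mode == "denatured" else 1.0)

    tables: list[ShiftTable] = []
    labels: list[str] = []
    for p in range(config.n_proteins):
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        path = _structure_path(length, config, rng)
        if config.mode == "denatured":
            keep = rng.random(length) < config.residual_structure_fraction
            path = "".join(s if k else "C" for s, k in zip(path, keep))
        residues = []
        for i in range(length):
            rt = types[rng.integers(len(types))]
            shifts = {}
            for atom in _FULL_SCHEME.atoms(rt):
                if rng.random() < config.missing_rate:
                    continue
                std = config.noise_std[_element(atom)] * noise_factor
                shifts[atom] = float(ref.mean(rt, atom, path[i])
                                     + rng.normal(0.0, std))
            residues.append(Residue(i + 1, rt, shifts))
        tables.append(ShiftTable(f"syn-{config.mode}-{p:03d}", residues))
        labels.append(path)
    return tables, labels


def generate_rank1(n_proteins: int = 20, length: int = 100,
                   seed: int = 42) -> list[ShiftTable]:
    """Noiseless dataset whose shifts vary along a single latent axis.

    Every atom's deviation from its coil mean is a fixed per-class scale
    times one scalar drawn per residue, so the standardized vectors lie
    exactly on a 1-D manifold: the idealized case a 1-D bottleneck can
    represent almost perfectly.
    """
    ref = build_reference()
    rng = np.random.default_rng(seed)
    scale = {"H": 0.2, "C": 1.5, "N": 2.5}
    types = sorted(STANDARD_RESIDUES)
    tables = []
    for p in range(n_proteins):
        residues = []
        for i in range(length):
            rt = types[rng.integers(len(types))]
            t = float(rng.uniform(-2.0, 2.0))
            shifts = {
                atom: ref.coil_mean[(rt, atom)] + t * scale[_element(atom)]
                for atom in _FULL_SCHEME.atoms(rt)
            }
            residues.append(Residue(i + 1, rt, shifts))
        tables.append(ShiftTable(f"syn-rank1-{p:03d}", residues))
    return tables


def write_fixtures(tables: Iterable[ShiftTable], format: str,
                   directory: str) -> list[str]:
    """Write each table as a NEF or NMR-STAR file; returns the paths."""
    if format not in ("nef", "nmrstar"):
        raise ValueError(f"unknown fixture format {format!r}")
    writer = write_nef if format == "nef" else write_nmrstar
    ext = "nef" if format == "nef" else "str"
    paths = []
    os.makedirs(directory, exist_ok=True)
    for table in tables:
        path = os.path.join(directory, f"{table.entry_id}.{ext}")
        with open(path, "w") as fh:
            fh.write(writer(table))
        paths.append(path)
    return paths
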