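"""Per-residue numeric encoding of chemical shifts.

A residue's shifts become a fixed-layout vector under one of three atom
schemes:

* ``full``    — backbone atoms plus the side-chain carbons, nitrogens and
  protons commonly assigned in BMRB entries (frozen table below),
* ``reduced`` — the backbone set H, HA, CA, N, CB, C (the default; robust
  when little side-chain data is available),
* ``dimers``  — CA, N and H only.

Glycine has no CB and its alpha protons are HA2/HA3, so its reduced layout
is [H, HA2, CA, N, C]; proline has no amide proton, so its layouts omit H
(except ``dimers``, where the H slot simply stays unobserved).

Standardization is per (residue type, atom): z = (ppm - mean) / std, with
mean/std fitted on a training corpus after discarding, per (type, atom),
values below the 1st or above the 99th percentile — a guard against
mis-referenced or mis-assigned shifts.  At inference, values outside the
stored percentile cutoffs are masked as missing rather than clipped.
Missing entries are encoded as 0 (the type-conditional mean) with a
companion binary mask so the model can ignore them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .shift_io import Residue, ShiftTable, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

SCHEME_NAMES = ("full", "reduced", "dimers")

_REDUCED_BASE = ["H", "HA", "CA", "N", "CB", "C"]

# Side-chain atoms added on top of the reduced backbone set for the full
# scheme.  Frozen, versioned with the package: the layout of every trained
# model depends on it.
_SIDECHAIN: dict[str, list[str]] = {
    "ALA": ["HB"],
    "ARG": ["CG", "CD", "HB2", "HB3", "HG2", "HG3", "HD2", "HD3", "NE", "HE"],
    "ASN": ["CG", "HB2", "HB3", "ND2", "HD21", "HD22"],
    "ASP": ["CG", "HB2", "HB3"],
    "CYS": ["HB2", "HB3"],
    "GLN": ["CG", "CD", "HB2", "HB3", "HG2", "HG3", "NE2", "HE21", "HE22"],
    "GLU": ["CG", "CD", "HB2", "HB3", "HG2", "HG3"],
    "GLY": ["HA3"],
    "HIS": ["CG", "CD2", "CE1", "HB2", "HB3", "HD2", "HE1"],
    "ILE": ["CG1", "CG2", "CD1", "HB", "HG12", "HG13", "HG2", "HD1"],
    "LEU": ["CG", "CD1", "CD2", "HB2", "HB3", "HG", "HD1", "HD2"],
    "LYS": ["CG", "CD", "CE", "HB2", "HB3", "HG2", "HG3", "HD2", "HD3",
            "HE2", "HE3"],
    "MET": ["CG", "CE", "HB2", "HB3", "HG2", "HG3", "HE"],
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "HB2", "HB3", "HD1",
            "HD2", "HE1", "HE2", "HZ"],
    "PRO": ["CG", "CD", "HB2", "HB3", "HG2", "HG3", "HD2", "HD3"],
    "SER": ["HB2", "HB3"],
    "THR": ["CG2", "HB", "HG2"],
    "TRP": ["CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2", "NE1",
            "HB2", "HB3", "HD1", "HE1", "HE3", "HZ2", "HZ3", "HH2"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "HB2", "HB3", "HD1",
            "HD2", "HE1", "HE2"],
    "VAL": ["CG1", "CG2", "HB", "HG1", "HG2"],
}


def _reduced_atoms(residue_type: str) -> list[str]:
    atoms = list(_REDUCED_BASE)
    if residue_type == "GLY":
        atoms = ["H", "HA2", "CA", "N", "C"]      # no CB; HA2 stands in for HA
    elif residue_type == "PRO":
        atoms = ["HA", "CA", "N", "CB", "C"]      # no amide proton
    return atoms


@dataclass(frozen=True)
class EncodingScheme:
    """A named, fixed atom layout per residue type."""

    name: str
    atoms_for: dict[str, tuple[str, ...]]

    def atoms(self, residue_type: str) -> tuple[str, ...]:
        return self.atoms_for[residue_type]


def build_scheme(name: str) -> EncodingScheme:
    """Return one of the three encoding schemes by name."""
    if name not in SCHEME_NAMES:
        raise ValueError(f"unknown encoding scheme {name!r}; "
                         f"choose one of {', '.join(SCHEME_NAMES)}")
    atoms_for: dict[str, tuple[str, ...]] = {}
    for rt in sorted(STANDARD_RESIDUES):
        if name == "dimers":
            atoms = ["CA", "N", "H"]
        elif name == "reduced":
            atoms = _reduced_atoms(rt)
        else:
            atoms = _reduced_atoms(rt) + _SIDECHAIN.get(rt, [])
        atoms_for[rt] = tuple(atoms)
    return EncodingScheme(name, atoms_for)


# ---------------------------------------------------------------------------
# Normalization statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomStats:
    mean: float
    std: float
    lower: float       # 1st-percentile cutoff of the training values
    upper: float       # 99th-percentile cutoff
    count: int         # surviving values the mean/std were computed on


@dataclass
class NormStats:
    """Per-(residue type, atom) standardization parameters."""

    scheme_name: str
    stats: dict[tuple[str, str], AtomStats] = field(default_factory=dict)

    def get(self, residue_type: str, atom: str) -> AtomStats | None:
        return self.stats.get((residue_type, atom))


def fit_norm_stats(tables: Iterable[ShiftTable], scheme: EncodingScheme,
                   min_count: int = 50) -> NormStats:
    """Fit percentile cutoffs and mean/std per (residue type, atom).

    For each (type, atom) pair of the scheme the training values are pooled
    across tables; the 1st and 99th empirical percentiles (linear
    interpolation between order statistics) become hard cutoffs, values
    outside them are discarded, and mean/std are computed on the survivors.
    Pairs with fewer than ``min_count`` observations, or degenerate spread,
    are dropped from the fitted statistics with a warning.
    """
    pooled: dict[tuple[str, str], list[float]] = {}
    n_tables = 0
    for table in tables:
        n_tables += 1
        for res in table:
            for atom in scheme.atoms(res.residue_type):
                v = res.shifts.get(atom)
                if v is not None:
                    pooled.setdefault((res.residue_type, atom), []).append(v)
    if n_tables == 0:
        raise ValueError("cannot fit normalization statistics on an empty corpus")

    out = NormStats(scheme.name)
    for key in sorted(pooled):
        values = np.asarray(pooled[key], dtype=float)
        if values.size < min_count:
            logger.warning("%s %s: only %d observations (< %d); atom dropped",
                           key[0], key[1], values.size, min_count)
            continue
        lower, upper = np.percentile(values, [1.0, 99.0])
        kept = values[(values >= lower) & (values <= upper)]
        std = float(kept.std())
        if std <= 0.0:
            logger.warning("%s %s: zero variance after percentile filter; atom dropped",
                           key[0], key[1])
            continue
        out.stats[key] = AtomStats(float(kept.mean()), std,
                                   float(lower), float(upper), int(kept.size))
    if not out.stats:
        raise ValueError("no (residue type, atom) pair had enough training data")
    return out


# ---------------------------------------------------------------------------
# Residue vectors
# ---------------------------------------------------------------------------

@dataclass
class ResidueVector:
    """Standardized shift vector in scheme layout plus observation mask."""

    values: np.ndarray
    mask: np.ndarray
    residue_type: str


def encode_residue(residue: Residue, scheme: EncodingScheme,
                   stats: NormStats) -> ResidueVector:
    """Standardize one residue's shifts into the scheme layout.

    Atoms that are missing, lack fitted statistics, or fall outside the
    stored percentile cutoffs are encoded as (0, mask=0).
    """
    atoms = scheme.atoms(residue.residue_type)
    values = np.zeros(len(atoms))
    mask = np.zeros(len(atoms))
    for k, atom in enumerate(atoms):
        st = stats.get(residue.residue_type, atom)
        v = residue.shifts.get(atom)
        if st is None or v is None:
            continue
        if v < st.lower or v > st.upper:
            continue        # outlier at inference: treated as missing
        values[k] = (v - st.mean) / st.std
        mask[k] = 1.0
    return ResidueVector(values, mask, residue.residue_type)


def encode_table(table: ShiftTable, scheme: EncodingScheme,
                 stats: NormStats) -> list[ResidueVector]:
    """Encode every residue of a table (order preserved)."""
    return [encode_residue(res, scheme, stats) for res in table]
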