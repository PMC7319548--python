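"""Reading and writing NMR chemical-shift data.

Input formats are the two STAR-syntax interchange formats used for NMR
assignments: NEF (``nef_chemical_shift_list`` save frames) and NMR-STAR,
both the 3.x ``_Atom_chem_shift`` loop and the legacy 2.1
``_Chem_shift_value`` dialect.  Only the assigned-chemical-shift content is
read; every other loop or save frame is skipped, so files with rich
metadata parse fine.

The in-memory model is :class:`ShiftTable`: an ordered list of residues,
each holding a map from atom nomenclature (CA, N, HB2, ...) to its chemical
shift in ppm.  One table describes one polymer chain; files containing
several chains or shift lists are reduced to the first one with a warning.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Amino-acid nomenclature
# ---------------------------------------------------------------------------

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_RESIDUES = frozenset(AA3_TO_1)


class ShiftFormatError(ValueError):
    """Raised when a shift file lacks the expected chemical-shift content."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One residue: author sequence number, 3-letter type, atom→ppm map."""

    seq_id: int
    residue_type: str
    shifts: dict[str, float] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        return AA3_TO_1[self.residue_type]


@dataclass
class ShiftTable:
    """Per-residue chemical shifts for a single protein chain.

    Residue numbering is the author numbering from the file; it may contain
    gaps but is strictly increasing.  ``sequence`` is the derived one-letter
    string, one character per residue present in the table.
    """

    entry_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class ProfileRecord:
    """Per-residue compressed shift values in [0, 1]; None marks missing."""

    entry_id: str
    seq_ids: list[int]
    sequence: str
    values: list[Optional[float]]

    def __post_init__(self) -> None:
        if not (len(self.seq_ids) == len(self.sequence) == len(self.values)):
            raise ValueError("profile fields must have equal length")
        for v in self.values:
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"profile value {v!r} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# STAR tokenizer and loop extraction
# ---------------------------------------------------------------------------

_LINE_TOKEN = re.compile(r"'([^']*)'|\"([^\"]*)\"|(\S+)")


def _tokenize(text: str) -> Iterator[str]:
    """Yield STAR tokens: bare, quoted, and semicolon-delimited values."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            block: list[str] = [line[1:]]
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            yield "\n".join(block)
            i += 1
            continue
        for m in _LINE_TOKEN.finditer(line):
            if m.group(3) is not None:
                tok = m.group(3)
                if tok.startswith("#"):
                    break
                yield tok
            elif m.group(1) is not None:
                yield m.group(1)
            else:
                yield m.group(2)
        i += 1


@dataclass
class _Loop:
    tags: list[str]          # lowercased
    rows: list[list[str]]
    frame: str               # enclosing save-frame name ("" at top level)


def _extract_loops(text: str) -> list[_Loop]:
    """Pull every loop out of a STAR document, ignoring non-loop content."""
    loops: list[_Loop] = []
    frame = ""
    toks = list(_tokenize(text))
    i = 0
    n = len(toks)
    while i < n:
        tok = toks[i]
        if tok == "save_":
            frame = ""
            i += 1
        elif tok.startswith("save_"):
            frame = tok[5:]
            i += 1
        elif tok == "loop_":
            i += 1
            tags: list[str] = []
            while i < n and toks[i].startswith("_"):
                tags.append(toks[i].lower())
                i += 1
            values: list[str] = []
            while i < n:
                t = toks[i]
                if t == "stop_":
                    i += 1
                    break
                if t in ("loop_", "save_") or t.startswith(("_", "save_", "data_")):
                    break
                values.append(t)
                i += 1
            rows = []
            if tags:
                width = len(tags)
                usable = len(values) - len(values) % width
                if usable != len(values):
                    logger.warning("loop %s: %d trailing values ignored",
                                   tags[0], len(values) - usable)
                rows = [values[k:k + width] for k in range(0, usable, width)]
            loops.append(_Loop(tags, rows, frame))
        else:
            i += 1
    return loops


def _column(loop: _Loop, *names: str) -> Optional[int]:
    """Index of the first tag whose suffix after '.' (or whole tag) matches."""
    for name in names:
        name = name.lower()
        for idx, tag in enumerate(loop.tags):
            suffix = tag.rsplit(".", 1)[-1].lstrip("_")
            if suffix == name:
                return idx
    return None


_NULL = {".", "?", ""}


def _rows_to_table(rows: Iterable[tuple[int, str, str, str]],
                   entry_id: str) -> ShiftTable:
    """Assemble (seq_id, comp, atom, value-string) rows into a ShiftTable."""
    by_seq: dict[int, Residue] = {}
    for seq_id, comp, atom, raw in rows:
        comp = comp.upper()
        if comp not in STANDARD_RESIDUES:
            logger.warning("entry %s: dropping non-standard residue %s %d",
                           entry_id, comp, seq_id)
            continue
        if not atom or atom in _NULL:
            continue
        try:
            value = float(raw)
        except ValueError:
            logger.warning("entry %s: unparsable shift %r for %s %d %s; atom skipped",
                           entry_id, raw, comp, seq_id, atom)
            continue
        if not math.isfinite(value):
            logger.warning("entry %s: non-finite shift for %s %d %s; atom skipped",
                           entry_id, comp, seq_id, atom)
            continue
        res = by_seq.get(seq_id)
        if res is None:
            res = by_seq[seq_id] = Residue(seq_id, comp)
        elif res.residue_type != comp:
            logger.warning("entry %s: conflicting residue type at %d (%s vs %s); keeping %s",
                           entry_id, seq_id, res.residue_type, comp, res.residue_type)
            continue
        if atom in res.shifts:
            logger.warning("entry %s: duplicate atom %s for residue %d; keeping first value",
                           entry_id, atom, seq_id)
            continue
        res.shifts[atom] = value
    residues = [by_seq[k] for k in sorted(by_seq)]
    return ShiftTable(entry_id, residues)


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def parse_nmrstar(text: str, entry_id: str = "entry") -> ShiftTable:
    """Parse an NMR-STAR document (3.x or 2.1 dialect) into a ShiftTable.

    Uses the first assigned-chemical-shift loop and, within it, the first
    chain (entity assembly) encountered; further loops/chains are skipped
    with a warning.  Non-amino-acid residues are dropped.
    """
    loops = _extract_loops(text)

    v3 = [lp for lp in loops
          if any(t.startswith("_atom_chem_shift.") for t in lp.tags)
          and _column(lp, "val") is not None]
    v2 = [lp for lp in loops if _column(lp, "chem_shift_value") is not None]

    if v3:
        if len(v3) > 1:
            logger.warning("entry %s: %d shift loops found; using the first",
                           entry_id, len(v3))
        loop = v3[0]
        c_seq = _column(loop, "comp_index_id", "seq_id")
        c_comp = _column(loop, "comp_id")
        c_atom = _column(loop, "atom_id")
        c_val = _column(loop, "val")
        c_chain = _column(loop, "entity_assembly_id", "entity_id")
        if c_seq is None or c_comp is None or c_atom is None:
            raise ShiftFormatError(
                "_Atom_chem_shift loop lacks Comp_index_ID/Comp_ID/Atom_ID tags")
        rows = _select_chain(loop.rows, c_chain, entry_id)
        return _rows_to_table(
            ((int(r[c_seq]), r[c_comp], r[c_atom], r[c_val])
             for r in rows if r[c_seq] not in _NULL),
            entry_id)

    if v2:
        if len(v2) > 1:
            logger.warning("entry %s: %d shift loops found; using the first",
                           entry_id, len(v2))
        loop = v2[0]
        c_seq = _column(loop, "residue_seq_code")
        c_comp = _column(loop, "residue_label")
        c_atom = _column(loop, "atom_name")
        c_val = _column(loop, "chem_shift_value")
        if c_seq is None or c_comp is None or c_atom is None:
            raise ShiftFormatError(
                "_Chem_shift_value loop lacks Residue_seq_code/Residue_label/Atom_name tags")
        return _rows_to_table(
            ((int(r[c_seq]), r[c_comp], r[c_atom], r[c_val])
             for r in loop.rows if r[c_seq] not in _NULL),
            entry_id)

    raise ShiftFormatError(
        "no assigned chemical shift loop found "
        "(expected an _Atom_chem_shift or _Chem_shift_value loop)")


def _select_chain(rows: list[list[str]], c_chain: Optional[int],
                  entry_id: str) -> list[list[str]]:
    if c_chain is None:
        return rows
    chains = [r[c_chain] for r in rows if r[c_chain] not in _NULL]
    if not chains:
        return rows
    first = chains[0]
    if any(c != first for c in chains):
        logger.warning("entry %s: multiple chains present; using chain %r",
                       entry_id, first)
    return [r for r in rows if r[c_chain] in _NULL or r[c_chain] == first]


def parse_nef(text: str, entry_id: str = "entry") -> ShiftTable:
    """Parse a NEF document's ``nef_chemical_shift_list`` into a ShiftTable.

    Pseudo-atom and wildcard names (HB%, QB, ...) are kept verbatim; whether
    they take part in the compression is decided by the encoding scheme's
    atom list.  Only the first chain of the first shift list is used.
    """
    loops = [lp for lp in _extract_loops(text)
             if any(t.startswith("_nef_chemical_shift.") for t in lp.tags)]
    if not loops:
        raise ShiftFormatError(
            "no nef_chemical_shift_list save frame with a _nef_chemical_shift loop found")
    if len(loops) > 1:
        logger.warning("entry %s: %d NEF shift lists found; using the first",
                       entry_id, len(loops))
    loop = loops[0]
    c_chain = _column(loop, "chain_code")
    c_seq = _column(loop, "sequence_code")
    c_comp = _column(loop, "residue_name")
    c_atom = _column(loop, "atom_name")
    c_val = _column(loop, "value")
    if c_seq is None or c_comp is None or c_atom is None or c_val is None:
        raise ShiftFormatError("_nef_chemical_shift loop lacks required tags")
    rows = _select_chain(loop.rows, c_chain, entry_id)

    def generate():
        for r in rows:
            if r[c_val] in _NULL:
                continue
            try:
                seq = int(r[c_seq])
            except ValueError:
                logger.warning("entry %s: non-integer sequence code %r skipped",
                               entry_id, r[c_seq])
                continue
            yield seq, r[c_comp], r[c_atom], r[c_val]

    return _rows_to_table(generate(), entry_id)


def parse_shift_file(path: str, entry_id: Optional[str] = None) -> ShiftTable:
    """Parse a file, auto-detecting NEF vs NMR-STAR by tag content."""
    with open(path) as fh:
        text = fh.read()
    if entry_id is None:
        entry_id = re.sub(r"\.[^.]*$", "", path.rsplit("/", 1)[-1])
    if "_nef_chemical_shift" in text:
        return parse_nef(text, entry_id)
    return parse_nmrstar(text, entry_id)


# ---------------------------------------------------------------------------
# Writers (fixture support and outputs)
# ---------------------------------------------------------------------------

def write_nmrstar(table: ShiftTable) -> str:
    """Serialize a ShiftTable as a minimal NMR-STAR 3.x document."""
    out = [f"data_{table.entry_id or 'shifts'}", "",
           "save_assigned_chemical_shifts",
           "   _Assigned_chem_shift_list.Sf_category  assigned_chemical_shifts",
           "   loop_",
           "      _Atom_chem_shift.ID",
           "      _Atom_chem_shift.Entity_assembly_ID",
           "      _Atom_chem_shift.Comp_index_ID",
           "      _Atom_chem_shift.Comp_ID",
           "      _Atom_chem_shift.Atom_ID",
           "      _Atom_chem_shift.Val"]
    row_id = 1
    for res in table.residues:
        for atom, value in res.shifts.items():
            out.append(f"      {row_id} 1 {res.seq_id} {res.residue_type} "
                       f"{atom} {value!r}")
            row_id += 1
    out += ["   stop_", "save_", ""]
    return "\n".join(out)


def write_nef(table: ShiftTable) -> str:
    """Serialize a ShiftTable as a minimal NEF document."""
    out = [f"data_{table.entry_id or 'shifts'}", "",
           "save_nef_chemical_shift_list_1",
           "   _nef_chemical_shift_list.sf_category   nef_chemical_shift_list",
           "   _nef_chemical_shift_list.sf_framecode  nef_chemical_shift_list_1",
           "   loop_",
           "      _nef_chemical_shift.chain_code",
           "      _nef_chemical_shift.sequence_code",
           "      _nef_chemical_shift.residue_name",
           "      _nef_chemical_shift.atom_name",
           "      _nef_chemical_shift.value"]
    for res in table.residues:
        for atom, value in res.shifts.items():
            out.append(f"      A {res.seq_id} {res.residue_type} {atom} {value!r}")
    out += ["   stop_", "save_", ""]
    return "\n".join(out)


def write_profile_json(profile: ProfileRecord, indent: Optional[int] = None) -> str:
    """Serialize a profile as JSON: entry_id + per-residue seq_id/aa/value."""
    obj = {
        "entry_id": profile.entry_id,
        "residues": [
            {"seq_id": s, "aa": a, "value": v}
            for s, a, v in zip(profile.seq_ids, profile.sequence, profile.values)
        ],
    }
    return json.dumps(obj, indent=indent)


def read_profile_json(text: str) -> ProfileRecord:
    """Inverse of :func:`write_profile_json`."""
    obj = json.loads(text)
    residues = obj["residues"]
    return ProfileRecord(
        entry_id=obj["entry_id"],
        seq_ids=[int(r["seq_id"]) for r in residues],
        sequence="".join(r["aa"] for r in residues),
        values=[None if r["value"] is None else float(r["value"]) for r in residues],
    )
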