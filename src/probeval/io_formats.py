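"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* FASTA (via Biopython) for RNA sequences; T is silently converted to U
  and sequences are upper-cased.
* A three-line dot-bracket dialect: ``>header`` / sequence / structure.
  Four independent bracket layers are recognised (``()``, ``[]``, ``{}``,
  ``<>``) so pseudoknotted annotations survive parsing; any non-dot
  symbol counts as "paired" downstream.
* Per-position event-count tables (TSV with ``#key=value`` metadata
  lines) holding read depth and stop/mutation event counts.
* Reactivity tables (TSV, same metadata convention).
* Base-pair probability matrices as sparse ``i<TAB>j<TAB>p`` TSV.
* PDB fixed-column ATOM/HETATM records (via Biopython), filtered to one
  chain, heavy atoms, and default altloc.

Positions are 1-based and inclusive in every file format; in-memory
arrays are 0-based numpy arrays (``positions[k]`` describes base
``k + 1``).  Missing per-position data are encoded as depth 0, never by
omitting rows: count tables must cover a contiguous 1..L range.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .errors import FormatError, ValidationError

RNA_ALPHABET = frozenset("ACGUN")

#: Bracket layers accepted in dot-bracket strings.  Each layer is matched
#: by its own stack, so crossing pairs between layers (pseudoknots) are
#: legal; crossings within a layer are not representable and therefore
#: cannot occur.
BRACKET_LAYERS = (("(", ")"), ("[", "]"), ("{", "}"), ("<", ">"))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnaRecord:
    """An RNA sequence with identifier, alphabet {A,C,G,U,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"RNA record {self.id!r} has empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"RNA record {self.id!r} contains non-RNA characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CountProfile:
    """Per-position sequencing event counts for one RNA and one channel.

    ``depth[i]`` is the number of reads informative at position ``i + 1``
    (1-based) and ``events[i]`` the number of stop or mutation events
    recorded there.  ``events <= depth`` everywhere; missing data are
    encoded as depth 0.
    """

    rna_id: str
    channel: str          # "plus" | "minus"
    mode: str             # "stop" | "mutation"
    bases: str
    depth: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.events = np.asarray(self.events, dtype=np.int64)
        if self.channel not in ("plus", "minus"):
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.mode not in ("stop", "mutation"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        L = len(self.bases)
        if self.depth.shape != (L,) or self.events.shape != (L,):
            raise ValidationError(
                f"profile {self.rna_id!r}: bases/depth/events lengths differ"
            )
        if (self.depth < 0).any() or (self.events < 0).any():
            raise ValidationError(f"profile {self.rna_id!r}: negative counts")
        bad = np.nonzero(self.events > self.depth)[0]
        if bad.size:
            raise ValidationError(
                f"profile {self.rna_id!r}: events > depth at position "
                f"{bad[0] + 1}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom from a PDB ATOM/HETATM record."""

    chain: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str          # "C" | "N" | "O" | "P" | "other"
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValidationError(
                f"atom {self.atom_name!r} in residue {self.residue_index} "
                "has non-finite coordinates"
            )

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _normalize_sequence(raw: str, path: Path, rec_id: str) -> str:
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        # locate the first offending line for the error message
        lineno = _find_line_with(path, bad)
        raise FormatError(
            f"{path}: record {rec_id!r} contains invalid characters "
            f"{sorted(bad)} (line {lineno})"
        )
    return seq


def _find_line_with(path: Path, bad: set[str]) -> int:
    probes = {c for b in bad for c in (b, b.lower())}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if probes & set(line.rstrip("\n")):
                return lineno
    return 0


def read_fasta(path: str | Path) -> list[RnaRecord]:
    """Read a FASTA file into :class:`RnaRecord` objects.

    Sequences are upper-cased and DNA-style T converted to U; anything
    outside {A,C,G,U,N} after conversion is a :class:`FormatError`.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_sequence(str(rec.seq), path, rec.id)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(RnaRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# Dot-bracket
# ---------------------------------------------------------------------------

def parse_dotbracket_pairs(structure: str) -> np.ndarray:
    """Return the 0-based partner array for a dot-bracket string.

    ``partner[i] == -1`` marks an unpaired position.  Each bracket layer
    is matched independently with its own stack.
    """
    partner = np.full(len(structure), -1, dtype=np.int64)
    stacks: dict[str, list[int]] = {open_: [] for open_, _ in BRACKET_LAYERS}
    closers = {close: open_ for open_, close in BRACKET_LAYERS}
    for i, sym in enumerate(structure):
        if sym == ".":
            continue
        if sym in stacks:
            stacks[sym].append(i)
        elif sym in closers:
            stack = stacks[closers[sym]]
            if not stack:
                raise FormatError(
                    f"unbalanced bracket {sym!r} at position {i + 1}"
                )
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        else:
            raise FormatError(
                f"unknown structure symbol {sym!r} at position {i + 1}"
            )
    for open_, stack in stacks.items():
        if stack:
            raise FormatError(
                f"unbalanced bracket {open_!r} at position {stack[-1] + 1}"
            )
    return partner


def read_dotbracket(path: str | Path) -> tuple[RnaRecord, str]:
    """Read a three-line dot-bracket file: header, sequence, structure."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) != 3:
        raise FormatError(
            f"{path}: expected 3 lines (header, sequence, structure), "
            f"found {len(lines)}"
        )
    header, seq_raw, structure = lines
    if not header.startswith(">"):
        raise FormatError(f"{path}: first line must start with '>'")
    rna_id = header[1:].split()[0] if header[1:].split() else header[1:]
    seq = seq_raw.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise FormatError(
            f"{path}: sequence contains invalid characters {sorted(bad)} "
            "(line 2)"
        )
    if len(seq) != len(structure):
        raise FormatError(
            f"{path}: sequence length {len(seq)} != structure length "
            f"{len(structure)}"
        )
    parse_dotbracket_pairs(structure)  # validates balance and symbols
    return RnaRecord(id=rna_id, sequence=seq), structure


def write_dotbracket(path: str | Path, rna: RnaRecord, structure: str) -> None:
    if len(structure) != len(rna):
        raise ValidationError("structure length does not match sequence")
    parse_dotbracket_pairs(structure)
    Path(path).write_text(f">{rna.id}\n{rna.sequence}\n{structure}\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def _read_metadata_and_table(path: Path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" not in stripped:
                    raise FormatError(
                        f"{path}: malformed metadata line {line.rstrip()!r}"
                    )
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
            elif line.strip():
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no table body")
    table = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t",
                        float_precision="round_trip")
    return meta, table


def _require_meta(meta: dict[str, str], key: str, path: Path) -> str:
    if key not in meta:
        raise FormatError(f"{path}: missing required metadata line '#{key}='")
    return meta[key]


def read_counts_tsv(path: str | Path) -> CountProfile:
    """Read a per-position count table.

    Required metadata lines: ``#rna=``, ``#mode=``, ``#channel=``.
    Required columns: position, base, depth, events.  Positions must be
    a contiguous 1..L range.
    """
    path = Path(path)
    meta, table = _read_metadata_and_table(path)
    mode = _require_meta(meta, "mode", path)
    channel = _require_meta(meta, "channel", path)
    rna_id = _require_meta(meta, "rna", path)
    required = ["position", "base", "depth", "events"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("position", "depth", "events"):
        if not pd.api.types.is_integer_dtype(table[col]):
            raise FormatError(f"{path}: column {col!r} is not integer-valued")
    pos = table["position"].to_numpy()
    L = len(pos)
    if not np.array_equal(pos, np.arange(1, L + 1)):
        raise FormatError(f"{path}: positions are not a contiguous 1..{L} range")
    bases = "".join(str(b).upper().replace("T", "U") for b in table["base"])
    try:
        return CountProfile(
            rna_id=rna_id,
            channel=channel,
            mode=mode,
            bases=bases,
            depth=table["depth"].to_numpy(),
            events=table["events"].to_numpy(),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_counts_tsv(path: str | Path, profile: CountProfile) -> None:
    with open(path, "w") as fh:
        fh.write(f"#rna={profile.rna_id}\n")
        fh.write(f"#mode={profile.mode}\n")
        fh.write(f"#channel={profile.channel}\n")
        fh.write("position\tbase\tdepth\tevents\n")
        for i in range(len(profile)):
            fh.write(
                f"{i + 1}\t{profile.bases[i]}\t{profile.depth[i]}\t"
                f"{profile.events[i]}\n"
            )


# ---------------------------------------------------------------------------
# Reactivity tables
# ---------------------------------------------------------------------------
# The ReactivityProfile type itself lives in reactivity_core; the table
# dialect is defined here with the other formats.  Imported lazily to
# avoid a module cycle.

def read_reactivity_tsv(path: str | Path):
    """Read a reactivity table into a ReactivityProfile."""
    from .reactivity_core import ReactivityProfile

    path = Path(path)
    meta, table = _read_metadata_and_table(path)
    mode = _require_meta(meta, "mode", path)
    rna_id = _require_meta(meta, "rna", path)
    background = _require_meta(meta, "background", path)
    probe = meta.get("probe") or None
    required = ["position", "base", "reactivity", "valid"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    pos = table["position"].to_numpy()
    L = len(pos)
    if not np.array_equal(pos, np.arange(1, L + 1)):
        raise FormatError(f"{path}: positions are not a contiguous 1..{L} range")
    valid_raw = table["valid"].astype(str).str.lower()
    if not valid_raw.isin(["true", "false"]).all():
        raise FormatError(f"{path}: column 'valid' must be true/false")
    valid = (valid_raw == "true").to_numpy()
    reactivity = table["reactivity"].to_numpy(dtype=float)
    bases = "".join(str(b).upper().replace("T", "U") for b in table["base"])
    return ReactivityProfile(
        rna_id=rna_id,
        bases=bases,
        reactivity=reactivity,
        valid=valid,
        mode=mode,
        probe=probe,
        background=background,
    )


def write_reactivity_tsv(path: str | Path, profile) -> None:
    with open(path, "w") as fh:
        fh.write(f"#rna={profile.rna_id}\n")
        fh.write(f"#mode={profile.mode}\n")
        if profile.probe is not None:
            fh.write(f"#probe={profile.probe}\n")
        fh.write(f"#background={profile.background}\n")
        fh.write("position\tbase\treactivity\tvalid\n")
        for i in range(len(profile.bases)):
            r = profile.reactivity[i]
            r_str = "nan" if np.isnan(r) else repr(float(r))
            v_str = "true" if profile.valid[i] else "false"
            fh.write(f"{i + 1}\t{profile.bases[i]}\t{r_str}\t{v_str}\n")


# ---------------------------------------------------------------------------
# Base-pair probability matrices
# ---------------------------------------------------------------------------

def read_bpp_tsv(path: str | Path):
    """Read a sparse ``i j p`` TSV (1-based) into a PairProbabilityMatrix.

    Required metadata: ``#rna=``, ``#length=``.
    """
    from .ensemble_bpp import PairProbabilityMatrix

    path = Path(path)
    meta, table = _read_metadata_and_table(path)
    rna_id = _require_meta(meta, "rna", path)
    length = int(_require_meta(meta, "length", path))
    required = ["i", "j", "probability"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    p = np.zeros((length, length), dtype=float)
    for i, j, prob in zip(table["i"], table["j"], table["probability"]):
        i, j = int(i), int(j)
        if not (1 <= i <= length and 1 <= j <= length) or i == j:
            raise FormatError(f"{path}: invalid pair indices ({i}, {j})")
        if not (0.0 <= prob <= 1.0):
            raise FormatError(f"{path}: probability out of [0,1] at ({i}, {j})")
        p[i - 1, j - 1] = prob
        p[j - 1, i - 1] = prob
    return PairProbabilityMatrix(rna_id=rna_id, p=p)


def write_bpp_tsv(path: str | Path, matrix) -> None:
    L = matrix.p.shape[0]
    with open(path, "w") as fh:
        fh.write(f"#rna={matrix.rna_id}\n")
        fh.write(f"#length={L}\n")
        fh.write("i\tj\tprobability\n")
        for i in range(L):
            for j in range(i + 1, L):
                if matrix.p[i, j] > 0:
                    fh.write(f"{i + 1}\t{j + 1}\t{matrix.p[i, j]!r}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_KNOWN_ELEMENTS = {"C", "N", "O", "P"}


def read_pdb_atoms(path: str | Path, chain: str) -> list[AtomRecord]:
    """Parse heavy atoms of one chain from a PDB file.

    Hydrogens/deuteriums, waters, and altlocs other than ' '/'A' are
    excluded.  Unresolved residues are simply absent; downstream
    operations treat missing residues as "accessibility unknown".
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate nonstandard toy files
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise FormatError(f"{path}: no models found") from None
    if chain not in [c.id for c in model]:
        raise ValidationError(
            f"{path}: chain {chain!r} not present "
            f"(available: {[c.id for c in model]})"
        )
    atoms: list[AtomRecord] = []
    for residue in model[chain]:
        if residue.get_resname().strip() == "HOH":
            continue
        for atom in residue:
            element = atom.element.strip().upper()
            if element in ("H", "D"):
                continue
            if atom.get_altloc() not in (" ", "A"):
                continue
            x, y, z = (float(v) for v in atom.coord)
            atoms.append(
                AtomRecord(
                    chain=chain,
                    residue_index=residue.get_id()[1],
                    residue_name=residue.get_resname().strip(),
                    atom_name=atom.get_name(),
                    element=element if element in _KNOWN_ELEMENTS else "other",
                    x=x,
                    y=y,
                    z=z,
                )
            )
    if not atoms:
        raise ValidationError(f"{path}: chain {chain!r} contains no heavy atoms")
    return atoms
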