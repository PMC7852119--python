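"""Reading molecule sets and building the positional pairing.

A comparison run takes two molecule-set files: the *original* molecules and
the molecules *predicted* for them (e.g. by a structure-recognition model),
where record ``i`` of one file corresponds to record ``i`` of the other.
Everything downstream depends on that positional mapping, so readers here
never skip, sort or deduplicate records: blank lines become placeholder
records and unparsable records are kept with a ``parse_failed`` status so
that line numbers stay aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from . import molgraph
from .molgraph import MolGraph, ParseError

log = logging.getLogger(__name__)


class RecordStatus(str, Enum):
    OK = "ok"
    PARSE_FAILED = "parse_failed"
    EMPTY = "empty"


@dataclass
class MoleculeRecord:
    """One positional record of a molecule-set file."""

    index: int
    raw: str
    name: Optional[str] = None
    status: RecordStatus = RecordStatus.OK
    graph: Optional[MolGraph] = None  # None unless status is OK

    def __post_init__(self) -> None:
        if self.status is not RecordStatus.OK:
            assert self.graph is None


@dataclass
class MoleculeSet:
    records: list[MoleculeRecord]
    source_path: str
    format: str  # "smiles" | "sdf"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_ok(self) -> int:
        return sum(1 for r in self.records if r.status is RecordStatus.OK)


@dataclass
class MoleculePair:
    index: int
    original: MoleculeRecord
    predicted: MoleculeRecord

    @property
    def valid(self) -> bool:
        return (
            self.original.status is RecordStatus.OK
            and self.predicted.status is RecordStatus.OK
        )


@dataclass
class PairedSet:
    pairs: list[MoleculePair]
    source_a: str = ""
    source_b: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_valid(self) -> int:
        return sum(1 for p in self.pairs if p.valid)

    @property
    def n_invalid(self) -> int:
        return len(self.pairs) - self.n_valid


class EmptySetError(ValueError):
    """Raised when a molecule-set file yields no records at all."""


class LengthMismatchError(ValueError):
    """Raised under the strict pairing policy when set sizes differ."""


def _parse_record(index: int, smiles: str, name: Optional[str]) -> MoleculeRecord:
    try:
        g = molgraph.parse_smiles(smiles)
    except ParseError:
        return MoleculeRecord(index, smiles, name, RecordStatus.PARSE_FAILED)
    return MoleculeRecord(index, smiles, name, RecordStatus.OK, g)


def read_smiles_set(path: str | Path, strip_names: bool = True) -> MoleculeSet:
    """Read a SMILES file: one record per line, UTF-8, LF or CRLF.

    When ``strip_names`` is true the first whitespace-separated token is the
    structure and the remainder of the line is kept as the record name.
    Blank lines become ``empty`` placeholder records so that line numbers of
    later records are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"molecule set file not found: {path}")
    records: list[MoleculeRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for index, line in enumerate(fh):
            line = line.rstrip("\r\n")
            stripped = line.strip()
            if not stripped:
                records.append(MoleculeRecord(index, line, None, RecordStatus.EMPTY))
                continue
            if strip_names:
                parts = stripped.split(None, 1)
                smiles = parts[0]
                name = parts[1] if len(parts) > 1 else None
            else:
                smiles, name = stripped, None
            records.append(_parse_record(index, smiles, name))
    if not records:
        raise EmptySetError(f"no records in {path}")
    return MoleculeSet(records, str(path), "smiles")


def read_sdf_set(path: str | Path) -> MoleculeSet:
    """Read an MDL SD file; one record per ``$$$$``-delimited block.

    The molfile title line becomes the record name.  A truncated or corrupt
    record gets status ``parse_failed`` and reading continues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"molecule set file not found: {path}")
    text = path.read_text(encoding="utf-8")
    blocks = text.split("$$$$")
    records: list[MoleculeRecord] = []
    for block in blocks:
        if not block.strip():
            continue
        block = block.lstrip("\r\n")
        index = len(records)
        title = block.splitlines()[0].strip() if block.splitlines() else ""
        name = title or None
        # strip SD data fields: the molfile ends at "M  END"
        end = block.find("M  END")
        molblock = block[: end + len("M  END")] if end >= 0 else block
        try:
            g = molgraph.parse_molblock(molblock)
        except ParseError:
            records.append(MoleculeRecord(index, block, name, RecordStatus.PARSE_FAILED))
            continue
        records.append(MoleculeRecord(index, block, name, RecordStatus.OK, g))
    if not records:
        raise EmptySetError(f"no records in {path}")
    return MoleculeSet(records, str(path), "sdf")


def read_set(path: str | Path, fmt: Optional[str] = None) -> MoleculeSet:
    """Dispatch on explicit format or on the file suffix (.sdf/.sd vs SMILES)."""
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".sd"} else "smiles"
    if fmt == "sdf":
        return read_sdf_set(path)
    if fmt == "smiles":
        return read_smiles_set(path)
    raise ValueError(f"unknown molecule set format: {fmt!r}")


def write_smiles_set(mset: MoleculeSet, path: str | Path) -> None:
    """Write a set back to SMILES text, preserving record order and blanks."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in mset.records:
            if rec.status is RecordStatus.EMPTY:
                fh.write("\n")
            elif rec.name:
                fh.write(f"{rec.raw} {rec.name}\n")
            else:
                fh.write(f"{rec.raw}\n")


def pair_sets(
    set_a: MoleculeSet, set_b: MoleculeSet, length_policy: str = "strict"
) -> PairedSet:
    """Join record ``i`` of ``set_a`` with record ``i`` of ``set_b``.

    ``strict`` requires equal lengths; ``truncate`` pairs up to the shorter
    length and logs the number of dropped trailing records.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise EmptySetError("cannot pair empty molecule sets")
    na, nb = len(set_a), len(set_b)
    if na != nb:
        if length_policy == "strict":
            raise LengthMismatchError(
                f"molecule sets differ in length: {na} vs {nb} records"
            )
        if length_policy != "truncate":
            raise ValueError(f"unknown length policy: {length_policy!r}")
        log.warning("length mismatch (%d vs %d): dropping %d trailing records",
                    na, nb, abs(na - nb))
    n = min(na, nb)
    pairs = [
        MoleculePair(i, set_a.records[i], set_b.records[i]) for i in range(n)
    ]
    return PairedSet(pairs, set_a.source_path, set_b.source_path)
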