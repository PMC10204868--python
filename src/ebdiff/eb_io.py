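"""Parse per-residue energy-breakdown score files and serialize them to CSV.

The input dialect is the whitespace-delimited ``SCORE:`` line format produced
by per-residue energy-decomposition runs: a header line naming the columns,
then one data line per interaction.  One-body rows (a residue's internal
energy) carry a placeholder partner token; two-body rows name a residue pair.
Each row decomposes the interaction into named score terms (fa_atr, fa_rep,
fa_sol, fa_elec, the hydrogen-bond classes, the disulfide term, ...) plus a
``total`` column, all in Rosetta Energy Units (REU).

Score-term columns are never hard-coded: the parser accepts any header, so
tables produced under different scoring functions load unchanged.  Totals are
stored exactly as read, never recomputed.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

__all__ = [
    "InteractionRecord",
    "EnergyTable",
    "BreakdownFormatError",
    "DuplicatePairError",
    "UnknownResidueError",
    "parse_breakdown",
    "write_csv",
    "read_csv",
    "net_residue_energy",
]

#: Placeholder tokens marking the partner fields of a one-body row.
DEFAULT_ONEBODY_TOKENS = ("--", "onebody")

#: Header columns that are not score terms.
_ID_COLUMNS = {
    "score", "pose_id", "resi1", "pdbid1", "restype1",
    "resi2", "pdbid2", "restype2", "description", "total",
}


class BreakdownFormatError(ValueError):
    """Malformed breakdown file; message carries the offending line number."""


class DuplicatePairError(ValueError):
    """The same residue pair (or one-body residue) appears twice."""


class UnknownResidueError(KeyError):
    """A residue id has no one-body record in the table."""


@dataclass
class InteractionRecord:
    """One row of a breakdown table: a residue pair or a one-body entry.

    ``resi2 is None`` marks a one-body record.  For two-body records the pair
    is normalized so that ``resi1 < resi2``.  ``terms`` maps score-term name
    to REU in header order; ``total`` is the row's total as read.
    """

    resi1: int
    restype1: str
    resi2: int | None
    restype2: str | None
    terms: dict[str, float]
    total: float

    @property
    def is_onebody(self) -> bool:
        return self.resi2 is None

    @property
    def pair(self) -> tuple[int, int]:
        if self.resi2 is None:
            raise ValueError("one-body record has no pair key")
        return (self.resi1, self.resi2)


@dataclass
class EnergyTable:
    """All interaction records for one structure.

    ``pair_index`` maps the normalized unordered pair key (i, j), i < j, to
    its record; ``onebody_index`` maps residue id to its one-body record.
    Duplicate keys are input errors, enforced by :meth:`add`.
    """

    term_names: list[str] = field(default_factory=list)
    records: list[InteractionRecord] = field(default_factory=list)
    pair_index: dict[tuple[int, int], InteractionRecord] = field(default_factory=dict)
    onebody_index: dict[int, InteractionRecord] = field(default_factory=dict)
    source_label: str = ""

    def add(self, rec: InteractionRecord) -> None:
        if rec.is_onebody:
            if rec.resi1 in self.onebody_index:
                raise DuplicatePairError(
                    f"duplicate one-body record for residue {rec.resi1}"
                )
            self.onebody_index[rec.resi1] = rec
        else:
            key = rec.pair
            if key in self.pair_index:
                raise DuplicatePairError(f"duplicate pair record for {key}")
            self.pair_index[key] = rec
        self.records.append(rec)

    @property
    def grand_total(self) -> float:
        """Sum of all one-body and two-body totals, in REU.

        Computed with exact (compensated) summation, so the value does not
        depend on record order.
        """
        total = math.fsum(r.total for r in self.records)
        if not math.isfinite(total):
            raise ValueError("grand total is not finite")
        return total

    @property
    def residues(self) -> list[int]:
        """Residue ids with a one-body record, ascending."""
        return sorted(self.onebody_index)

    def restype_of(self, residue: int) -> str:
        """Three-letter type of a residue, from its one-body record."""
        try:
            return self.onebody_index[residue].restype1
        except KeyError:
            raise UnknownResidueError(
                f"residue {residue} has no one-body record in table "
                f"{self.source_label!r}"
            )

    def pairs_of(self, residue: int) -> list[InteractionRecord]:
        """All two-body records involving a residue."""
        return [
            r for (i, j), r in self.pair_index.items()
            if i == residue or j == residue
        ]


def _parse_number(token: str, lineno: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise BreakdownFormatError(
            f"line {lineno}: non-numeric value {token!r} in column {column!r}"
        )


def parse_breakdown(
    file_text: str,
    source_label: str = "",
    onebody_tokens: tuple[str, ...] = DEFAULT_ONEBODY_TOKENS,
) -> EnergyTable:
    """Parse breakdown score-file text into an :class:`EnergyTable`.

    The first ``SCORE:`` line naming ``resi1`` is the header; term names are
    taken from it verbatim, in order.  Two-body pairs are normalized to
    ``resi1 < resi2``.  The placeholder token set marking one-body partner
    fields is configurable because it varies across producer versions.
    """
    header: list[str] | None = None
    col: dict[str, int] = {}
    term_names: list[str] = []
    table: EnergyTable | None = None

    for lineno, line in enumerate(file_text.splitlines(), start=1):
        if not line.startswith("SCORE:"):
            continue
        tokens = line.split()[1:]
        if header is None:
            if "resi1" not in tokens:
                continue  # e.g. a pose-level score line before the header
            header = tokens
            col = {name: i for i, name in enumerate(header)}
            for required in ("resi1", "restype1", "resi2", "restype2", "total"):
                if required not in col:
                    raise BreakdownFormatError(
                        f"line {lineno}: header is missing column {required!r}"
                    )
            term_names = [t for t in header if t not in _ID_COLUMNS]
            table = EnergyTable(term_names=term_names, source_label=source_label)
            continue

        if len(tokens) != len(header):
            raise BreakdownFormatError(
                f"line {lineno}: expected {len(header)} columns, got {len(tokens)}"
            )
        resi1 = int(_parse_number(tokens[col["resi1"]], lineno, "resi1"))
        restype1 = tokens[col["restype1"]]
        resi2_tok = tokens[col["resi2"]]
        restype2_tok = tokens[col["restype2"]]
        terms = {
            name: _parse_number(tokens[col[name]], lineno, name)
            for name in term_names
        }
        total = _parse_number(tokens[col["total"]], lineno, "total")

        if resi2_tok in onebody_tokens or restype2_tok in onebody_tokens:
            rec = InteractionRecord(resi1, restype1, None, None, terms, total)
        else:
            resi2 = int(_parse_number(resi2_tok, lineno, "resi2"))
            restype2 = restype2_tok
            if resi2 < resi1:
                resi1, resi2 = resi2, resi1
                restype1, restype2 = restype2, restype1
            rec = InteractionRecord(resi1, restype1, resi2, restype2, terms, total)
        try:
            table.add(rec)
        except DuplicatePairError as exc:
            raise DuplicatePairError(f"line {lineno}: {exc}")

    if table is None:
        raise BreakdownFormatError(
            "no header line found (expected a SCORE: line naming resi1)"
        )
    return table


_ONEBODY_CSV = ("--", "onebody")


def write_csv(t: EnergyTable, path_or_buffer=None) -> str:
    """Write an energy table as RFC-4180 CSV; returns the CSV text.

    Columns: resi1, restype1, resi2, restype2, every term in header order,
    total.  One-body rows use the ``--``/``onebody`` placeholders.  Floats
    are written at full precision so a reload is bit-exact.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["resi1", "restype1", "resi2", "restype2", *t.term_names, "total"]
    )
    for rec in t.records:
        resi2 = _ONEBODY_CSV[0] if rec.is_onebody else rec.resi2
        restype2 = _ONEBODY_CSV[1] if rec.is_onebody else rec.restype2
        writer.writerow(
            [rec.resi1, rec.restype1, resi2, restype2]
            + [repr(rec.terms[name]) for name in t.term_names]
            + [repr(rec.total)]
        )
    text = buf.getvalue()
    if path_or_buffer is not None:
        if hasattr(path_or_buffer, "write"):
            path_or_buffer.write(text)
        else:
            try:
                with open(path_or_buffer, "w", newline="") as fh:
                    fh.write(text)
            except OSError as exc:
                raise OSError(f"cannot write CSV to {path_or_buffer}: {exc}")
    return text


def read_csv(csv_text: str, source_label: str = "") -> EnergyTable:
    """Re-read a CSV produced by :func:`write_csv`."""
    reader = csv.reader(io.StringIO(csv_text))
    try:
        header = next(reader)
    except StopIteration:
        raise BreakdownFormatError("empty CSV: missing header row")
    fixed = ["resi1", "restype1", "resi2", "restype2"]
    if header[: len(fixed)] != fixed or header[-1] != "total":
        raise BreakdownFormatError(f"unexpected CSV header {header!r}")
    term_names = header[len(fixed):-1]
    table = EnergyTable(term_names=term_names, source_label=source_label)
    for lineno, row in enumerate(reader, start=2):
        if len(row) != len(header):
            raise BreakdownFormatError(
                f"line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        resi1 = int(row[0])
        terms = {name: float(v) for name, v in zip(term_names, row[4:-1])}
        total = float(row[-1])
        if row[2] in _ONEBODY_CSV or row[3] in _ONEBODY_CSV:
            rec = InteractionRecord(resi1, row[1], None, None, terms, total)
        else:
            rec = InteractionRecord(resi1, row[1], int(row[2]), row[3], terms, total)
        table.add(rec)
    return table


def net_residue_energy(
    t: EnergyTable, residue: int, half_pair: bool = False
) -> float:
    """Net interaction energy of a residue, in REU.

    One-body total plus the totals of every pair interaction the residue
    participates in.  By default each pair contributes its full total to both
    members; with ``half_pair`` each member is charged half, so the sum of
    net energies over all residues equals the table's grand total.
    """
    if residue not in t.onebody_index:
        raise UnknownResidueError(
            f"residue {residue} has no one-body record in table "
            f"{t.source_label!r}"
        )
    factor = 0.5 if half_pair else 1.0
    pair_sum = sum(r.total for r in t.pairs_of(residue))
    return t.onebody_index[residue].total + factor * pair_sum


def net_residue_energies(t: EnergyTable, half_pair: bool = False) -> dict[int, float]:
    """Net interaction energy for every residue in the table."""
    factor = 0.5 if half_pair else 1.0
    net = {i: rec.total for i, rec in t.onebody_index.items()}
    for (i, j), rec in t.pair_index.items():
        if i in net:
            net[i] += factor * rec.total
        if j in net:
            net[j] += factor * rec.total
    return net
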