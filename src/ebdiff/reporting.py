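"""Energy-difference matrix, per-term breakdowns and consolidated CSV reports.

The residue-pair difference matrix is the data behind the usual
mutant-vs-reference heatmap: a sparse symmetric map (i, j) → ΔE in REU,
masked at a significance threshold.  It is exported long-form (one row per
surviving pair) because protein-sized matrices are overwhelmingly empty; a
dense export exists for small systems.  All report files are deterministic
for fixed inputs and parameters — timestamps live only in the run manifest.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .interaction_diff import (
    PAIR_CATEGORIES,
    TYPE_ORDER,
    DiffResult,
    significant_changes,
    summary_table,
)
from .residue_depth import JoinedDepthRecord

__all__ = [
    "DiffMatrix",
    "build_matrix",
    "per_term_breakdown",
    "write_matrix_csv",
    "read_matrix_csv",
    "full_report",
]

#: Per-term deltas smaller than this are dropped from breakdown listings.
ZERO_TERM_EPS = 1e-9


@dataclass
class DiffMatrix:
    """Sparse symmetric matrix of significant pair energy changes."""

    n: int
    entries: dict[tuple[int, int], float] = field(default_factory=dict)
    threshold: float = 0.0

    def get(self, i: int, j: int, default: float | None = None) -> float | None:
        """Entry for an unordered pair; (j, i) returns the same value."""
        return self.entries.get((min(i, j), max(i, j)), default)

    def dense(self):
        """Dense symmetric n×n numpy array (zeros where masked)."""
        import numpy as np

        m = np.zeros((self.n, self.n))
        for (i, j), v in self.entries.items():
            m[i - 1, j - 1] = v
            m[j - 1, i - 1] = v
        return m


def build_matrix(d: DiffResult, n: int, threshold: float = 0.0) -> DiffMatrix:
    """Build the difference matrix from a diff, masking at ``threshold``.

    Entries are exactly the significant changes at the same threshold
    (strict inequality); masked pairs are absent, not zero.
    """
    _, significant = significant_changes(d, threshold=threshold)
    entries = {}
    for ch in significant:
        i, j = ch.pair
        if j > n or i < 1:
            raise ValueError(
                f"pair {ch.pair} is outside the residue range 1..{n}"
            )
        entries[ch.pair] = ch.delta_total
    return DiffMatrix(n=n, entries=entries, threshold=threshold)


def per_term_breakdown(
    d: DiffResult, pair: tuple[int, int]
) -> list[tuple[str, float]]:
    """Ordered per-term energy deltas of one changed pair, zero terms removed.

    Terms appear in the breakdown-file header order; terms whose |delta| is
    below :data:`ZERO_TERM_EPS` are omitted for clarity.
    """
    change = d.change_for(pair)  # raises KeyError for unknown pairs
    order = [t for t in d.term_names if t in change.delta_terms]
    order += [t for t in change.delta_terms if t not in order]
    listed = [
        (t, change.delta_terms[t])
        for t in order
        if abs(change.delta_terms[t]) > ZERO_TERM_EPS
    ]
    if not listed:
        warnings.warn(
            f"pair {pair} is marked changed but every per-term delta is zero",
            stacklevel=2,
        )
    return listed


def write_matrix_csv(m: DiffMatrix, path=None, dense: bool = False) -> str:
    """Serialize a matrix as CSV; long-form (resi1, resi2, delta) by default.

    The dense form writes the full n×n grid and is intended for small
    systems only.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    if dense:
        writer.writerow(["resi"] + [str(j) for j in range(1, m.n + 1)])
        grid = m.dense()
        for i in range(m.n):
            writer.writerow([i + 1] + [repr(float(v)) for v in grid[i]])
    else:
        writer.writerow(["resi1", "resi2", "delta_total"])
        for (i, j) in sorted(m.entries):
            writer.writerow([i, j, repr(m.entries[(i, j)])])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_matrix_csv(csv_text: str, n: int, threshold: float = 0.0) -> DiffMatrix:
    """Rebuild a :class:`DiffMatrix` from its long-form CSV."""
    reader = csv.reader(io.StringIO(csv_text))
    header = next(reader)
    if header != ["resi1", "resi2", "delta_total"]:
        raise ValueError(f"unexpected matrix CSV header {header!r}")
    entries = {}
    for row in reader:
        entries[(int(row[0]), int(row[1]))] = float(row[2])
    return DiffMatrix(n=n, entries=entries, threshold=threshold)


def _interaction_rows(d: DiffResult) -> list[list]:
    rows = []
    for ch in d.changes:
        rows.append(
            [
                ch.pair[0],
                ch.restypes_ref[0] or "",
                ch.restypes_mut[0] or "",
                ch.pair[1],
                ch.restypes_ref[1] or "",
                ch.restypes_mut[1] or "",
                str(ch.category),
                ";".join(sorted(str(t) for t in ch.types)),
                *[repr(ch.delta_terms.get(t, 0.0)) for t in d.term_names],
                repr(ch.delta_total),
            ]
        )
    return rows


def full_report(
    d: DiffResult,
    depths: list[JoinedDepthRecord] | None,
    out_dir,
    threshold: float = 1.0,
    n_residues: int | None = None,
    parameters: dict | None = None,
    version: str | None = None,
    dense_matrix: bool = False,
) -> dict[str, Path]:
    """Write the consolidated CSV reports plus a JSON run manifest.

    Produces ``interactions.csv`` (every changed pair with category, types
    and per-term deltas), ``summary.csv`` (the category × type grid of
    significant-change counts and sums), ``matrix.csv`` (the long-form
    difference matrix at ``threshold``), ``onebody.csv``, optionally
    ``depth.csv`` when joined depth records are given, and ``manifest.json``
    recording inputs, parameters, version and timestamp.  Data files contain
    no timestamps, so repeated runs on the same inputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, header: list[str], rows: list[list]) -> None:
        path = out / name
        try:
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh, lineterminator="\n")
                w.writerow(header)
                w.writerows(rows)
        except OSError as exc:
            raise OSError(f"cannot write report file {path}: {exc}")
        written[name] = path

    _write(
        "interactions.csv",
        [
            "resi1", "restype_ref1", "restype_mut1",
            "resi2", "restype_ref2", "restype_mut2",
            "category", "types",
            *[f"delta_{t}" for t in d.term_names],
            "delta_total",
        ],
        _interaction_rows(d),
    )

    grid = summary_table(d, threshold=threshold)
    _write(
        "summary.csv",
        ["category"]
        + [f"count_{t}" for t in TYPE_ORDER]
        + [f"sum_{t}" for t in TYPE_ORDER],
        [
            [str(cat)]
            + [grid[(cat, t)][0] for t in TYPE_ORDER]
            + [repr(grid[(cat, t)][1]) for t in TYPE_ORDER]
            for cat in PAIR_CATEGORIES
        ],
    )

    if n_residues is None:
        ids = [resi for ch in d.changes for resi in ch.pair]
        ids += [resi for resi, _ in d.onebody_changes]
        n_residues = max(ids, default=0)
    matrix = build_matrix(d, n=n_residues, threshold=threshold)
    written["matrix.csv"] = out / "matrix.csv"
    write_matrix_csv(matrix, written["matrix.csv"], dense=dense_matrix)

    _write(
        "onebody.csv",
        ["residue", "delta_total"],
        [[resi, repr(delta)] for resi, delta in d.onebody_changes],
    )

    if depths is not None:
        _write(
            "depth.csv",
            [
                "residue", "restype_ref", "restype_mut",
                "depth_ref", "depth_mut", "net_ref", "net_mut",
                "delta_net", "missing_in",
            ],
            [
                [
                    r.residue, r.restype_ref or "", r.restype_mut or "",
                    "" if r.depth_ref is None else repr(r.depth_ref),
                    "" if r.depth_mut is None else repr(r.depth_mut),
                    "" if r.net_ref is None else repr(r.net_ref),
                    "" if r.net_mut is None else repr(r.net_mut),
                    "" if r.delta_net is None else repr(r.delta_net),
                    r.missing_in or "",
                ]
                for r in depths
            ],
        )

    sig_sum, sig_list = significant_changes(d, threshold=threshold)
    manifest = {
        "tool": "ebdiff",
        "version": version,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "parameters": dict(parameters or {}),
        "threshold": threshold,
        "n_residues": n_residues,
        "n_changes": len(d.changes),
        "n_significant": len(sig_list),
        "significant_sum": sig_sum,
        "n_onebody_changes": len(d.onebody_changes),
        "mutations": [str(m) for m in d.mutations],
        "files": sorted(written),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    written["manifest.json"] = manifest_path
    return written
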