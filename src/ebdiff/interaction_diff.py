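"""Diff two energy tables and classify every changed pairwise interaction.

Given per-residue energy breakdowns of a reference structure and a designed
mutant (under the same 1..N renumbering) plus the list of mutations, every
residue-pair interaction that changed is assigned to one of six categories:

=========  =========================  ==========================
category   interacting in             pair involves a mutation?
=========  =========================  ==========================
A          both structures            no   (indirect change)
B          both structures            yes
C          reference only (lost)      no
D          reference only (lost)      yes
E          mutant only (gained)       no
F          mutant only (gained)       yes
=========  =========================  ==========================

and to a set of physical interaction types (salt bridge, disulfide, the four
hydrogen-bond classes, and the catch-all "all") inferred from score terms and
residue types.  Energy differences are reported in REU (mutant − reference);
negative deltas stabilize the mutant.  Changes whose magnitude exceeds a
threshold (default 1.0 REU, strict inequality) are "significant": summing
only those keeps thousands of tiny changes from masking chemically important
ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .eb_io import EnergyTable, InteractionRecord
from .structure_io import Mutation, one_to_three

__all__ = [
    "InteractionCategory",
    "InteractionType",
    "PairChange",
    "DiffResult",
    "CategoryStateError",
    "RenumberingMismatchError",
    "is_interacting",
    "classify_category",
    "classify_type",
    "diff_tables",
    "total_energy_changes",
    "significant_changes",
    "summary_table",
]

#: Default tolerance below which a table entry counts as "not interacting".
DEFAULT_PRESENCE_EPS = 1e-9
#: Default tolerance below which a both-sides energy difference is "unchanged".
DEFAULT_CHANGE_EPS = 1e-6
#: Default significance threshold in REU (strict inequality).
DEFAULT_THRESHOLD = 1.0


class InteractionCategory(enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    ONEBODY_CHANGE = "onebody"

    def __str__(self) -> str:
        return self.value


#: Categories describing two-body changes, in report order.
PAIR_CATEGORIES = (
    InteractionCategory.A,
    InteractionCategory.B,
    InteractionCategory.C,
    InteractionCategory.D,
    InteractionCategory.E,
    InteractionCategory.F,
)


class InteractionType(enum.Enum):
    SALT_BRIDGE = "salt_bridge"
    DISULFIDE = "disulfide"
    HB_SC_SC = "hb_sc_sc"
    HB_BB_SC = "hb_bb_sc"
    HB_BB_SR = "hb_bb_sr"
    HB_BB_LR = "hb_bb_lr"
    ALL = "all"

    def __str__(self) -> str:
        return self.value


#: Interaction types in report order ("all" last).
TYPE_ORDER = (
    InteractionType.SALT_BRIDGE,
    InteractionType.DISULFIDE,
    InteractionType.HB_SC_SC,
    InteractionType.HB_BB_SC,
    InteractionType.HB_BB_SR,
    InteractionType.HB_BB_LR,
    InteractionType.ALL,
)

_BASIC = {"ARG", "LYS", "HIS"}
_BASIC_STRICT = {"ARG", "LYS"}
_ACIDIC = {"ASP", "GLU"}


class CategoryStateError(ValueError):
    """A pair was reported as interacting in neither structure."""


class RenumberingMismatchError(ValueError):
    """Residue types in the tables contradict the mutation list."""


@dataclass
class PairChange:
    """A changed pairwise interaction between reference and mutant."""

    pair: tuple[int, int]
    restypes_ref: tuple[str | None, str | None]
    restypes_mut: tuple[str | None, str | None]
    category: InteractionCategory
    delta_terms: dict[str, float]
    delta_total: float
    types: frozenset[InteractionType]
    involves_mutation: bool


@dataclass
class DiffResult:
    """All changed interactions between a reference and a mutant table."""

    changes: list[PairChange] = field(default_factory=list)
    onebody_changes: list[tuple[int, float]] = field(default_factory=list)
    mutations: list[Mutation] = field(default_factory=list)
    presence_eps: float = DEFAULT_PRESENCE_EPS
    change_eps: float = DEFAULT_CHANGE_EPS
    term_names: list[str] = field(default_factory=list)

    def change_for(self, pair: tuple[int, int]) -> PairChange:
        key = (min(pair), max(pair))
        for ch in self.changes:
            if ch.pair == key:
                return ch
        raise KeyError(f"pair {key} is not among the changed interactions")


def is_interacting(
    t: EnergyTable,
    pair: tuple[int, int],
    presence_eps: float = DEFAULT_PRESENCE_EPS,
) -> bool:
    """Whether a residue pair interacts in a table.

    Producers of breakdown tables omit pairs outside the interaction graph,
    so absence from the table is the natural non-interaction signal; a
    recorded pair whose |total| does not exceed ``presence_eps`` also counts
    as non-interacting.
    """
    key = (min(pair), max(pair))
    rec = t.pair_index.get(key)
    return rec is not None and abs(rec.total) > presence_eps


def classify_category(
    in_ref: bool,
    in_mut: bool,
    involves_mutation: bool,
    delta_total: float,
    change_eps: float = DEFAULT_CHANGE_EPS,
) -> InteractionCategory | None:
    """Assign a changed pair to one of the categories A-F.

    Returns ``None`` for a pair present on both sides whose energy difference
    is within ``change_eps`` (an unchanged interaction).  Pairs where both
    members are mutated count as mutation-involving (B/D/F).
    """
    if not in_ref and not in_mut:
        raise CategoryStateError(
            "pair interacts in neither structure; no category applies"
        )
    if in_ref and in_mut:
        if abs(delta_total) <= change_eps:
            return None
        return InteractionCategory.B if involves_mutation else InteractionCategory.A
    if in_ref:
        return InteractionCategory.D if involves_mutation else InteractionCategory.C
    return InteractionCategory.F if involves_mutation else InteractionCategory.E


def classify_type(
    record: InteractionRecord,
    restypes: tuple[str, str] | None = None,
    strict_salt_bridge: bool = False,
) -> set[InteractionType]:
    """Physical interaction types of a two-body record.

    Hydrogen-bond classes fire when the corresponding score term is negative
    (hbond_sc, hbond_bb_sc, hbond_sr_bb, hbond_lr_bb).  A disulfide requires
    two cysteines with a non-zero disulfide term.  A salt bridge requires
    oppositely charged side chains (ARG/LYS/HIS vs ASP/GLU; strict mode drops
    HIS from the basic set) with an active side-chain hydrogen-bond term —
    an operational criterion built from the score decomposition, since
    geometric salt-bridge detection is outside the scope of a score-file
    analysis.  Every pair belongs to "all".
    """
    if record.is_onebody:
        raise ValueError("interaction types are defined for two-body records only")
    if restypes is None:
        restypes = (record.restype1, record.restype2)
    r1, r2 = (r.upper() for r in restypes)
    terms = record.terms
    types = {InteractionType.ALL}
    if terms.get("hbond_sc", 0.0) < 0.0:
        types.add(InteractionType.HB_SC_SC)
    if terms.get("hbond_bb_sc", 0.0) < 0.0:
        types.add(InteractionType.HB_BB_SC)
    if terms.get("hbond_sr_bb", 0.0) < 0.0:
        types.add(InteractionType.HB_BB_SR)
    if terms.get("hbond_lr_bb", 0.0) < 0.0:
        types.add(InteractionType.HB_BB_LR)
    if r1 == "CYS" and r2 == "CYS" and terms.get("dslf_fa13", 0.0) != 0.0:
        types.add(InteractionType.DISULFIDE)
    basic = _BASIC_STRICT if strict_salt_bridge else _BASIC
    charged = (r1 in basic and r2 in _ACIDIC) or (r2 in basic and r1 in _ACIDIC)
    if charged and terms.get("hbond_sc", 0.0) < 0.0:
        types.add(InteractionType.SALT_BRIDGE)
    return types


def _check_mutations(
    ref: EnergyTable, mut: EnergyTable, mutations: list[Mutation]
) -> None:
    for m in mutations:
        for table, letter, side in (
            (ref, m.ref_restype, "reference"),
            (mut, m.mut_restype, "mutant"),
        ):
            if m.position not in table.onebody_index:
                raise RenumberingMismatchError(
                    f"mutation {m}: position {m.position} has no one-body "
                    f"record in the {side} table"
                )
            expected = one_to_three(letter)
            found = table.restype_of(m.position).upper()
            if found != expected:
                raise RenumberingMismatchError(
                    f"mutation {m}: {side} table has {found} at position "
                    f"{m.position}, expected {expected}"
                )


def _restypes_at(table: EnergyTable, pair: tuple[int, int]) -> tuple:
    rec = table.pair_index.get(pair)
    if rec is not None:
        return (rec.restype1, rec.restype2)
    return (
        table.restype_of(pair[0]) if pair[0] in table.onebody_index else None,
        table.restype_of(pair[1]) if pair[1] in table.onebody_index else None,
    )


def diff_tables(
    ref: EnergyTable,
    mut: EnergyTable,
    mutations: list[Mutation],
    presence_eps: float = DEFAULT_PRESENCE_EPS,
    change_eps: float = DEFAULT_CHANGE_EPS,
    strict_salt_bridge: bool = False,
) -> DiffResult:
    """Diff a reference and a mutant table into categorized pair changes.

    Walks the union of pair keys in both tables.  Each pair that interacts on
    at least one side and whose energy changed becomes one :class:`PairChange`
    with category, per-term deltas (mutant − reference; a missing side is the
    zero vector) and interaction types — evaluated on the side where the pair
    exists, and as the union of both sides for A/B pairs, so a bond present
    in only one structure is still reported.  One-body totals that differ by
    more than ``change_eps`` are reported separately.

    Changes are sorted ascending by delta (most stabilizing first), ties
    broken by pair key, so reports are deterministic.
    """
    _check_mutations(ref, mut, mutations)
    mutated = {m.position for m in mutations}

    changes: list[PairChange] = []
    for key in set(ref.pair_index) | set(mut.pair_index):
        rec_ref = ref.pair_index.get(key)
        rec_mut = mut.pair_index.get(key)
        in_ref = rec_ref is not None and abs(rec_ref.total) > presence_eps
        in_mut = rec_mut is not None and abs(rec_mut.total) > presence_eps
        if not in_ref and not in_mut:
            continue
        total_ref = rec_ref.total if rec_ref is not None else 0.0
        total_mut = rec_mut.total if rec_mut is not None else 0.0
        delta_total = total_mut - total_ref
        involves = key[0] in mutated or key[1] in mutated
        category = classify_category(in_ref, in_mut, involves, delta_total, change_eps)
        if category is None:
            continue

        term_names = sorted(
            set(rec_ref.terms if rec_ref else ()) | set(rec_mut.terms if rec_mut else ())
        )
        delta_terms = {
            name: (rec_mut.terms.get(name, 0.0) if rec_mut else 0.0)
            - (rec_ref.terms.get(name, 0.0) if rec_ref else 0.0)
            for name in term_names
        }
        types: set[InteractionType] = set()
        if in_ref:
            types |= classify_type(rec_ref, strict_salt_bridge=strict_salt_bridge)
        if in_mut:
            types |= classify_type(rec_mut, strict_salt_bridge=strict_salt_bridge)
        changes.append(
            PairChange(
                pair=key,
                restypes_ref=_restypes_at(ref, key),
                restypes_mut=_restypes_at(mut, key),
                category=category,
                delta_terms=delta_terms,
                delta_total=delta_total,
                types=frozenset(types),
                involves_mutation=involves,
            )
        )
    changes.sort(key=lambda ch: (ch.delta_total, ch.pair))

    onebody_changes = []
    for resi in sorted(set(ref.onebody_index) | set(mut.onebody_index)):
        ob_ref = ref.onebody_index.get(resi)
        ob_mut = mut.onebody_index.get(resi)
        delta = (ob_mut.total if ob_mut else 0.0) - (ob_ref.total if ob_ref else 0.0)
        if abs(delta) > change_eps:
            onebody_changes.append((resi, delta))

    term_names = list(ref.term_names)
    for name in mut.term_names:
        if name not in term_names:
            term_names.append(name)
    return DiffResult(
        changes=changes,
        onebody_changes=onebody_changes,
        mutations=list(mutations),
        presence_eps=presence_eps,
        change_eps=change_eps,
        term_names=term_names,
    )


def _select(
    d: DiffResult, categories
) -> list[PairChange]:
    if categories is None:
        return list(d.changes)
    cats = {InteractionCategory(c) if not isinstance(c, InteractionCategory) else c
            for c in categories}
    if not cats:
        raise ValueError("category selection must be non-empty")
    return [ch for ch in d.changes if ch.category in cats]


def total_energy_changes(d: DiffResult, categories=None) -> float:
    """Sum of all pair energy changes in the selected categories, in REU.

    Includes every change however small; compare with
    :func:`significant_changes`, which keeps only the large ones.
    """
    return sum(ch.delta_total for ch in _select(d, categories))


def significant_changes(
    d: DiffResult,
    categories=None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, list[PairChange]]:
    """Sum and list of significant pair changes in the selected categories.

    A change is significant when it is larger than +threshold or smaller
    than −threshold REU (strict inequalities; a change of exactly ±threshold
    is excluded).  The list is sorted ascending by delta, most stabilizing
    first.  At threshold 0 this reduces to :func:`total_energy_changes`.
    """
    if threshold < 0:
        raise ValueError("significance threshold must be non-negative")
    kept = [
        ch for ch in _select(d, categories)
        if ch.delta_total > threshold or ch.delta_total < -threshold
    ]
    kept.sort(key=lambda ch: (ch.delta_total, ch.pair))
    return sum(ch.delta_total for ch in kept), kept


def summary_table(
    d: DiffResult, threshold: float = DEFAULT_THRESHOLD
) -> dict[tuple[InteractionCategory, InteractionType], tuple[int, float]]:
    """Count and sum significant changes per (category, interaction type).

    Returns a dense grid over categories A-F × all interaction types; a pair
    with several hydrogen-bond types contributes to each of its type cells
    but only once to the "all" column.
    """
    grid = {
        (cat, typ): (0, 0.0) for cat in PAIR_CATEGORIES for typ in TYPE_ORDER
    }
    _, significant = significant_changes(d, threshold=threshold)
    for ch in significant:
        for typ in ch.types:
            count, total = grid[(ch.category, typ)]
            grid[(ch.category, typ)] = (count + 1, total + ch.delta_total)
    return grid
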