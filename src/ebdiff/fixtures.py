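"""Synthetic, ground-truth-labelled inputs for the whole analysis chain.

Two generators:

* :func:`make_toy_structure` builds ideal-geometry toy structures (helix,
  extended chain, or a layered atom ball for depth tests) with stub
  side-chain atoms, serialized as PDB text.
* :func:`make_mock_breakdown` emits a *pair* of energy-breakdown score files
  (reference and mutant) in the whitespace ``SCORE:`` dialect whose pair
  presence/absence, mutation involvement, score terms and totals realize an
  exactly planted plan: so many category-A changes, so many category-F salt
  bridges, and so on.  The planted labels, per-pair deltas, significance
  flags and independently accumulated grand totals are returned alongside
  the file text, so the diff machinery can be validated against known truth.

The energies are bookkeeping constructs, not physical: totals are exact sums
of their score terms, and planted deltas are drawn from ±[1.2, 4.0] REU
(clearly significant) or ±[0.05, 0.9] REU (clearly insignificant), with the
band [0.9, 1.2] left empty so tests near the ±1.0 REU significance threshold
are never decided by floating-point luck.  Exact-boundary behaviour is
exercised with hand-written values elsewhere.

All randomness flows from one explicitly seeded generator per plan; no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interaction_diff import InteractionCategory, InteractionType
from .structure_io import (
    Atom,
    Mutation,
    Residue,
    Structure,
    one_to_three,
    write_pdb,
)

__all__ = [
    "FixturePlan",
    "PlantedChange",
    "MockBreakdown",
    "InfeasiblePlanError",
    "make_toy_structure",
    "make_mock_breakdown",
    "random_plan",
]

#: Score-term columns of the mock breakdown files, in header order.
MOCK_TERMS = [
    "fa_atr", "fa_rep", "fa_sol", "fa_elec",
    "hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc", "dslf_fa13",
]

_SIGNIFICANT_BAND = (1.2, 4.0)
_INSIGNIFICANT_BAND = (0.05, 0.9)

_AA20 = list("ACDEFGHIKLMNPQRSTVWY")
# letters safe for "no specific type fires" roles (apolar / small polar,
# never part of the salt-bridge charge sets)
_NEUTRAL = list("AFGILMPVW")

_CATEGORY_ORDER = "ABCDEF"


class InfeasiblePlanError(ValueError):
    """The requested plan cannot be realized (e.g. B pairs but no mutations)."""


@dataclass
class FixturePlan:
    """Recipe for one reference/mutant mock-breakdown pair.

    ``mutations`` may be an integer count (positions and residue types are
    chosen by the generator), a list of positions, or fully specified
    :class:`~ebdiff.structure_io.Mutation` objects.  ``category_counts`` maps
    category letters A-F to the number of planted changes; ``type_mix`` gives
    the sampling weights of intended interaction types for planted pairs
    ("all" means no specific physical type).
    """

    n_residues: int = 60
    mutations: int | list = 8
    category_counts: dict = field(
        default_factory=lambda: {"A": 6, "B": 6, "C": 5, "D": 5, "E": 5, "F": 5}
    )
    type_mix: dict = field(
        default_factory=lambda: {
            "salt_bridge": 0.10,
            "disulfide": 0.05,
            "hb_sc_sc": 0.15,
            "hb_bb_sc": 0.10,
            "hb_bb_sr": 0.10,
            "hb_bb_lr": 0.10,
            "all": 0.40,
        }
    )
    delta_scale: float = 1.0
    seed: int = 0
    n_background_pairs: int = 40
    significant_fraction: float = 0.6


@dataclass(frozen=True)
class PlantedChange:
    """Ground truth for one planted pair change."""

    pair: tuple[int, int]
    category: InteractionCategory
    types: frozenset[InteractionType]
    delta_total: float
    significant: bool


@dataclass
class MockBreakdown:
    """Generator output: file texts plus independently bookkept truth."""

    ref_text: str
    mut_text: str
    planted: list[PlantedChange]
    mutations: list[Mutation]
    ref_sequence: str
    mut_sequence: str
    grand_total_ref: float  # accumulated while writing, not via parsing
    grand_total_mut: float
    onebody_deltas: dict[int, float]

    @property
    def planted_by_pair(self) -> dict[tuple[int, int], PlantedChange]:
        return {p.pair: p for p in self.planted}


# --------------------------------------------------------------------------
# toy structures
# --------------------------------------------------------------------------

# core constellation (N/CA/C/O/CB stub), centered so the mean offset is
# zero: a residue's mean-atom depth then has no orientation bias
_CORE_OFFSETS = [
    # name, element, local offset in Å
    ("N", "N", (-1.32, 0.12, -0.46)),
    ("CA", "C", (-0.12, -0.48, -0.06)),
    ("C", "C", (1.08, 0.12, 0.34)),
    ("O", "O", (1.18, 1.32, 0.34)),
    ("CB", "C", (-0.12, -1.98, 0.24)),
]

# boundary-shell residues of the ball carry two tangential rings of stub
# atoms, projected onto the sphere of the residue's radius: the outermost
# layer then forms a nearly smooth closed shell, so the probe cannot reach
# interior voids and depth grows cleanly and stably with burial
_RING_SPECS = [(1.65, 6, 0.0), (3.3, 12, 0.26)]  # (arc radius Å, count, phase)

_BALL_LAYER_STEP = 1.5  # Å between concentric layers
_BALL_LAYER_CAPS = [1, 3, 7, 12, 17, 20, 26, 33, 40, 48]
_BALL_RADIAL_SPREAD = 0.7  # Å of within-layer radial stagger (breaks ties)
_BALL_JITTER = 0.05  # Å of coordinate jitter (breaks symmetry)


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _residue_centers(
    n: int, geometry: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Residue center positions plus a boundary-shell flag per residue."""
    outer = np.zeros(n, dtype=bool)
    if geometry == "helix":
        i = np.arange(n)
        angle = np.deg2rad(100.0) * i
        return np.column_stack(
            [2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i]
        ), outer
    if geometry == "extended":
        i = np.arange(n)
        return np.column_stack([3.5 * i, np.zeros(n), np.zeros(n)]), outer
    if geometry == "ball":
        if n > sum(_BALL_LAYER_CAPS):
            raise InfeasiblePlanError(
                f"ball geometry supports at most {sum(_BALL_LAYER_CAPS)} "
                f"residues, got {n}"
            )
        centers = []
        remaining = n
        filled = 0
        for layer, cap in enumerate(_BALL_LAYER_CAPS):
            k = min(cap, remaining)
            if k <= 0:
                break
            r = _BALL_LAYER_STEP * layer
            if r == 0.0:
                centers.append(np.zeros((1, 3)))
            else:
                # stagger radii within the layer so burial ranks are distinct
                rr = r + np.linspace(-_BALL_RADIAL_SPREAD, _BALL_RADIAL_SPREAD, k)
                centers.append(_fibonacci_directions(k) * rr[:, None])
            remaining -= k
            filled += k
            outer[:] = False
            outer[filled - k: filled] = True  # last occupied layer so far
        pts = np.concatenate(centers, axis=0)
        return pts + rng.normal(scale=_BALL_JITTER, size=pts.shape), outer
    raise ValueError(f"unknown geometry {geometry!r}; use helix, extended or ball")


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.eye(3)[int(np.argmin(np.abs(u)))]
    t1 = np.cross(u, e)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(u, t1)


def _boundary_ring_atoms(center: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    radius = float(np.linalg.norm(center))
    u = center / radius
    t1, t2 = _tangent_frame(u)
    atoms = []
    k = 0
    for arc_r, count, phase in _RING_SPECS:
        for m in range(count):
            ang = 2.0 * np.pi * m / count + phase
            p = center + arc_r * (np.cos(ang) * t1 + np.sin(ang) * t2)
            p = radius * p / np.linalg.norm(p)  # keep the shell spherical
            atoms.append((f"S{k}", "C", p))
            k += 1
    return atoms


def make_toy_structure(
    n_residues: int,
    geometry: str = "helix",
    sequence: str | None = None,
    seed: int = 0,
) -> tuple[Structure, str]:
    """Build a toy structure and its PDB text.

    The backbone follows an idealized parametric path (alpha-helical rise of
    1.5 Å/residue, 3.5 Å/residue extended chain, or concentric layers for
    the "ball" used by depth tests); each residue carries N/CA/C/O plus a CB
    stub (except glycine).  In the ball, boundary-layer residues
    additionally carry tangential stub-atom rings that close the outer
    shell.  Output is deterministic for a given seed.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(_AA20, size=n_residues))
    if len(sequence) != n_residues:
        raise ValueError(
            f"sequence length {len(sequence)} does not match n_residues {n_residues}"
        )
    centers, boundary = _residue_centers(n_residues, geometry, rng)
    residues = []
    for idx, (letter, center) in enumerate(zip(sequence, centers), start=1):
        restype3 = one_to_three(letter)
        offsets = [
            (name, elem, off) for name, elem, off in _CORE_OFFSETS
            if not (name == "CB" and restype3 == "GLY")
        ]
        atoms = [
            Atom(name=name, element=elem,
                 x=float(center[0] + dx), y=float(center[1] + dy),
                 z=float(center[2] + dz))
            for name, elem, (dx, dy, dz) in offsets
        ]
        if boundary[idx - 1] and float(np.linalg.norm(center)) > 1.0:
            atoms += [
                Atom(name=name, element=elem,
                     x=float(p[0]), y=float(p[1]), z=float(p[2]))
                for name, elem, p in _boundary_ring_atoms(center)
            ]
        residues.append(
            Residue(chain_id="A", author_seq_id=idx, renumbered_id=idx,
                    restype3=restype3, atoms=atoms)
        )
    s = Structure(residues=residues, source_label=f"toy-{geometry}-{seed}")
    return s, write_pdb(s)


# --------------------------------------------------------------------------
# mock breakdown tables
# --------------------------------------------------------------------------

class _RestypeLedger:
    """Tracks per-residue restype constraints on the ref and mut sides.

    Unmutated residues share one restype across both sides; mutated residues
    must end up with different types on the two sides.
    """

    def __init__(self, n: int, mutated: set[int]):
        self.n = n
        self.mutated = mutated
        self.ref: dict[int, str] = {}
        self.mut: dict[int, str] = {}

    def get(self, side: str, i: int) -> str | None:
        return (self.ref if side == "ref" else self.mut).get(i)

    def compatible(self, side: str, i: int, code3: str) -> bool:
        own = self.get(side, i)
        if own is not None and own != code3:
            return False
        if i in self.mutated:
            other = self.get("mut" if side == "ref" else "ref", i)
            if other is not None and other == code3:
                return False  # mutation requires different types per side
        return True

    def require(self, side: str, i: int, code3: str) -> None:
        if not self.compatible(side, i, code3):
            raise InfeasiblePlanError(
                f"restype conflict at residue {i} ({side} side, {code3})"
            )
        if i in self.mutated:
            (self.ref if side == "ref" else self.mut)[i] = code3
        else:
            self.ref[i] = code3
            self.mut[i] = code3

    def finalize(self, rng: np.random.Generator) -> tuple[list[str], list[str]]:
        ref_seq, mut_seq = [], []
        for i in range(1, self.n + 1):
            r = self.ref.get(i)
            m = self.mut.get(i)
            if i not in self.mutated:
                code = r or m or one_to_three(str(rng.choice(_NEUTRAL)))
                r = m = code
            else:
                if r is None:
                    pool = [one_to_three(a) for a in _AA20]
                    pool = [c for c in pool if c != m]
                    r = str(rng.choice(pool))
                if m is None:
                    pool = [one_to_three(a) for a in _AA20]
                    pool = [c for c in pool if c != r]
                    m = str(rng.choice(pool))
            ref_seq.append(r)
            mut_seq.append(m)
        return ref_seq, mut_seq


# per intended type: admissible restype combinations (or None when any
# residue types will do) and the score term that realizes it, with the
# extra types that fire as a side effect of the construction
_TYPE_RECIPES = {
    "salt_bridge": dict(
        restypes=[("ARG", "ASP"), ("LYS", "GLU"), ("ARG", "GLU"),
                  ("LYS", "ASP")],
        term="hbond_sc",
        fires={InteractionType.SALT_BRIDGE, InteractionType.HB_SC_SC},
    ),
    "disulfide": dict(
        restypes=[("CYS", "CYS")], term="dslf_fa13",
        fires={InteractionType.DISULFIDE},
    ),
    "hb_sc_sc": dict(
        # polar but never basic-vs-acidic, so no salt bridge can fire
        restypes=[("SER", "THR"), ("THR", "ASN"), ("SER", "GLN"),
                  ("ASN", "TYR")],
        term="hbond_sc",
        fires={InteractionType.HB_SC_SC},
    ),
    "hb_bb_sc": dict(
        restypes=None, term="hbond_bb_sc", fires={InteractionType.HB_BB_SC},
    ),
    "hb_bb_sr": dict(
        restypes=None, term="hbond_sr_bb", fires={InteractionType.HB_BB_SR},
    ),
    "hb_bb_lr": dict(
        restypes=None, term="hbond_lr_bb", fires={InteractionType.HB_BB_LR},
    ),
    "all": dict(restypes=None, term=None, fires=set()),
}


def _normalize_mutations(plan: FixturePlan, rng: np.random.Generator):
    """Return (positions, preset ref letters, preset mut letters)."""
    spec = plan.mutations
    if isinstance(spec, int):
        if spec > plan.n_residues:
            raise InfeasiblePlanError("more mutations than residues")
        positions = sorted(
            int(p) for p in rng.choice(plan.n_residues, size=spec, replace=False) + 1
        )
        return positions, {}, {}
    if all(isinstance(m, Mutation) for m in spec):
        positions = sorted(m.position for m in spec)
        ref = {m.position: one_to_three(m.ref_restype) for m in spec}
        mut = {m.position: one_to_three(m.mut_restype) for m in spec}
        return positions, ref, mut
    positions = sorted(int(p) for p in spec)
    return positions, {}, {}


def _draw_delta(rng: np.random.Generator, significant: bool, scale: float) -> float:
    lo, hi = _SIGNIFICANT_BAND if significant else _INSIGNIFICANT_BAND
    magnitude = rng.uniform(lo, hi) * scale
    return float(magnitude if rng.random() < 0.5 else -magnitude)


def _base_terms(rng: np.random.Generator) -> dict[str, float]:
    """Generic (no specific type) nonzero interaction terms."""
    t = {name: 0.0 for name in MOCK_TERMS}
    t["fa_atr"] = -float(rng.uniform(0.2, 1.5))
    t["fa_rep"] = float(rng.uniform(0.0, 0.3))
    t["fa_sol"] = float(rng.uniform(0.0, 0.4))
    t["fa_elec"] = float(rng.uniform(-0.3, 0.3))
    return t


def _with_type_term(
    terms: dict[str, float], recipe: dict, rng: np.random.Generator
) -> dict[str, float]:
    t = dict(terms)
    if recipe["term"] is not None:
        t[recipe["term"]] = -float(rng.uniform(0.5, 1.5))
    return t


def _set_total(terms: dict[str, float], total: float) -> dict[str, float]:
    """Adjust fa_atr so the term sum equals the requested total exactly."""
    t = dict(terms)
    t["fa_atr"] += total - sum(t.values())
    return t


def _format_table(
    rows: list[tuple[int, str, int | None, str | None, dict, float]],
) -> str:
    # full float precision (repr) so parsed values and bookkept sums agree
    # to well below 1e-9 and CSV round trips are bit-exact
    header = (
        "SCORE:     pose_id          resi1 pdbid1 restype1          "
        "resi2 pdbid2 restype2 "
        + " ".join(f"{t:>24s}" for t in MOCK_TERMS)
        + f" {'total':>24s} description"
    )
    lines = [header]
    for resi1, rt1, resi2, rt2, terms, total in rows:
        if resi2 is None:
            r2, p2, t2 = "--", "--", "onebody"
            desc = f"{rt1}_{resi1}_onebody"
        else:
            r2, p2, t2 = str(resi2), f"{resi2}A", rt2
            desc = f"{rt1}_{resi1}-{rt2}_{resi2}"
        lines.append(
            f"SCORE:           1 {resi1:14d} {resi1:>5d}A {rt1:>8s} "
            f"{r2:>14s} {p2:>6s} {t2:>8s} "
            + " ".join(f"{terms[t]!r:>24s}" for t in MOCK_TERMS)
            + f" {total!r:>24s} {desc}"
        )
    return "\n".join(lines) + "\n"


def make_mock_breakdown(plan: FixturePlan) -> MockBreakdown:
    """Generate a reference/mutant breakdown-file pair realizing a plan.

    Every planted category change is constructed explicitly: presence or
    absence of the pair record on each side, mutation involvement of its
    members, an intended interaction type realized through residue types and
    score terms, and a delta drawn from the significant or insignificant
    band.  Totals are exact term sums; grand totals are accumulated
    independently of the table objects while the rows are written.

    Raises :class:`InfeasiblePlanError` when the plan cannot be realized
    (mutation-involving categories without mutations, more pairs than the
    residue count affords, or unsatisfiable residue-type constraints).
    """
    rng = np.random.default_rng(plan.seed)
    n = plan.n_residues
    counts = {
        str(InteractionCategory(c)): int(v)
        for c, v in plan.category_counts.items()
    }
    for letter in _CATEGORY_ORDER:
        counts.setdefault(letter, 0)
    n_planted = sum(counts.values())
    if n_planted > n * (n - 1) // 2:
        raise InfeasiblePlanError("more planted pairs than residue pairs available")

    positions, preset_ref, preset_mut = _normalize_mutations(plan, rng)
    mutated = set(positions)
    needs_mut = counts["B"] + counts["D"] + counts["F"]
    if needs_mut > 0 and not mutated:
        raise InfeasiblePlanError(
            "categories B/D/F require mutations, but the plan has none"
        )
    if len(mutated) >= n - 1 and (counts["A"] + counts["C"] + counts["E"]) > 0:
        raise InfeasiblePlanError(
            "categories A/C/E require at least two unmutated residues"
        )

    ledger = _RestypeLedger(n, mutated)
    for p, code in preset_ref.items():
        ledger.require("ref", p, code)
    for p, code in preset_mut.items():
        ledger.require("mut", p, code)

    type_names = list(plan.type_mix)
    weights = np.asarray([plan.type_mix[t] for t in type_names], dtype=float)
    if weights.sum() <= 0:
        raise InfeasiblePlanError("type_mix weights must sum to a positive value")
    weights = weights / weights.sum()

    unmutated = [i for i in range(1, n + 1) if i not in mutated]
    used_pairs: set[tuple[int, int]] = set()
    planted: list[PlantedChange] = []
    # rows destined for each file: (resi1, rt1, resi2, rt2, terms, total)
    plans_ref: list[dict] = []
    plans_mut: list[dict] = []

    def eval_sides(letter: str) -> list[str]:
        return {"A": ["ref", "mut"], "B": ["mut"], "C": ["ref"],
                "D": ["ref"], "E": ["mut"], "F": ["mut"]}[letter]

    def pick_pair(letter: str, recipe: dict) -> tuple[int, int]:
        sides = eval_sides(letter)
        pool_a = positions if letter in "BDF" else unmutated
        pool_b = unmutated if unmutated else list(range(1, n + 1))

        def compat(i: int, code3: str | None) -> bool:
            if code3 is None:
                return True
            return all(ledger.compatible(side, i, code3) for side in sides)

        combos: list[tuple[str | None, str | None]] = []
        if recipe["restypes"] is None:
            combos.append((None, None))
        else:
            for ra, rb in recipe["restypes"]:
                combos.append((ra, rb))
                if ra != rb:
                    combos.append((rb, ra))
        def ordered(pool: list[int], code: str | None) -> list[int]:
            # prefer residues already carrying the required type: reusing
            # them keeps the unconstrained pool from being exhausted
            if code is None:
                return [int(i) for i in rng.permutation(pool)]
            reuse, fresh = [], []
            for i in pool:
                if not compat(i, code):
                    continue
                if any(ledger.get(s, i) == code for s in sides):
                    reuse.append(i)
                else:
                    fresh.append(i)
            return [int(i) for i in rng.permutation(reuse)] + \
                   [int(i) for i in rng.permutation(fresh)]

        for ci in rng.permutation(len(combos)):
            code_a, code_b = combos[int(ci)]
            for a in ordered(pool_a, code_a):
                for b in ordered(pool_b, code_b):
                    if a == b:
                        continue
                    key = (min(a, b), max(a, b))
                    if key in used_pairs:
                        continue
                    if code_a is not None:
                        for side in sides:
                            ledger.require(side, a, code_a)
                            ledger.require(side, b, code_b)
                    used_pairs.add(key)
                    return a, b
        raise InfeasiblePlanError(
            f"could not place a category-{letter} pair with type constraints "
            f"{recipe['restypes']}; plan too dense for {n} residues"
        )

    work: list[tuple[str, str]] = []
    for letter in _CATEGORY_ORDER:
        for _ in range(counts[letter]):
            work.append((letter, str(rng.choice(type_names, p=weights))))
    # place residue-type-constrained pairs first, while the ledger is loose
    work.sort(key=lambda item: _TYPE_RECIPES[item[1]]["restypes"] is None)

    for letter, intended in work:
            recipe = _TYPE_RECIPES[intended]
            a, b = pick_pair(letter, recipe)
            significant = bool(rng.random() < plan.significant_fraction)
            delta = _draw_delta(rng, significant, plan.delta_scale)

            if letter in ("A", "B"):
                ref_terms = _base_terms(rng)
                if letter == "A" and recipe["term"] is not None:
                    ref_terms = _with_type_term(ref_terms, recipe, rng)
                ref_total = sum(ref_terms.values())
                if abs(ref_total) < 1e-6:  # keep the pair "interacting" in ref
                    ref_terms["fa_atr"] -= 0.1
                    ref_total = sum(ref_terms.values())
                # the pair must still count as interacting in the mutant
                while abs(ref_total + delta) < 1e-6:
                    delta = _draw_delta(rng, significant, plan.delta_scale)
                mut_terms = _with_type_term(ref_terms, recipe, rng) \
                    if letter == "B" else dict(ref_terms)
                mut_terms = _set_total(mut_terms, ref_total + delta)
                plans_ref.append(dict(pair=(a, b), terms=ref_terms))
                plans_mut.append(dict(pair=(a, b), terms=mut_terms))
            elif letter in ("C", "D"):
                # present in ref only; losing it contributes −ref_total
                ref_terms = _with_type_term(_base_terms(rng), recipe, rng)
                ref_terms = _set_total(ref_terms, -delta)
                plans_ref.append(dict(pair=(a, b), terms=ref_terms))
            else:  # E, F: present in mut only
                mut_terms = _with_type_term(_base_terms(rng), recipe, rng)
                mut_terms = _set_total(mut_terms, delta)
                plans_mut.append(dict(pair=(a, b), terms=mut_terms))

            truth_types = {InteractionType.ALL} | recipe["fires"]
            planted.append(
                PlantedChange(
                    pair=(min(a, b), max(a, b)),
                    category=InteractionCategory(letter),
                    types=frozenset(truth_types),
                    delta_total=delta,
                    significant=significant,
                )
            )

    # unchanged background pairs, identical on both sides
    for _ in range(plan.n_background_pairs):
        for _attempt in range(200):
            a, b = (int(x) for x in rng.choice(n, size=2, replace=False) + 1)
            key = (min(a, b), max(a, b))
            if key not in used_pairs:
                used_pairs.add(key)
                break
        else:
            break
        terms = _base_terms(rng)
        plans_ref.append(dict(pair=key, terms=terms))
        plans_mut.append(dict(pair=key, terms=dict(terms)))

    ref_codes, mut_codes = ledger.finalize(rng)
    ref3 = {i: c for i, c in enumerate(ref_codes, start=1)}
    mut3 = {i: c for i, c in enumerate(mut_codes, start=1)}

    from .structure_io import three_to_one

    mutations = [
        Mutation(position=p, ref_restype=three_to_one(ref3[p]),
                 mut_restype=three_to_one(mut3[p]))
        for p in positions
    ]
    ref_sequence = "".join(three_to_one(ref3[i]) for i in range(1, n + 1))
    mut_sequence = "".join(three_to_one(mut3[i]) for i in range(1, n + 1))

    # one-body rows: identical for unmutated residues, shifted for mutated
    onebody_deltas: dict[int, float] = {}
    rows_ref, rows_mut = [], []
    grand_ref = 0.0
    grand_mut = 0.0
    for i in range(1, n + 1):
        terms = _base_terms(rng)
        total = sum(terms.values())
        rows_ref.append((i, ref3[i], None, None, terms, total))
        grand_ref += total
        if i in mutated:
            d = float(rng.uniform(0.05, 0.9) * (1 if rng.random() < 0.5 else -1))
            mterms = _set_total(terms, total + d)
            onebody_deltas[i] = d
            rows_mut.append((i, mut3[i], None, None, mterms, total + d))
            grand_mut += total + d
        else:
            rows_mut.append((i, ref3[i], None, None, dict(terms), total))
            grand_mut += total

    for entry in plans_ref:
        (a, b), terms = entry["pair"], entry["terms"]
        total = sum(terms.values())
        rows_ref.append((min(a, b), ref3[min(a, b)], max(a, b), ref3[max(a, b)],
                         terms, total))
        grand_ref += total
    for entry in plans_mut:
        (a, b), terms = entry["pair"], entry["terms"]
        total = sum(terms.values())
        rows_mut.append((min(a, b), mut3[min(a, b)], max(a, b), mut3[max(a, b)],
                         terms, total))
        grand_mut += total

    return MockBreakdown(
        ref_text=_format_table(rows_ref),
        mut_text=_format_table(rows_mut),
        planted=planted,
        mutations=mutations,
        ref_sequence=ref_sequence,
        mut_sequence=mut_sequence,
        grand_total_ref=grand_ref,
        grand_total_mut=grand_mut,
        onebody_deltas=onebody_deltas,
    )


def random_plan(
    seed: int,
    n_residues: int = 60,
    n_mutations: int | None = None,
    n_pairs: int = 38,
    **overrides,
) -> FixturePlan:
    """A randomized but feasible plan: ``n_pairs`` split across A-F.

    When ``n_mutations`` is not given it scales with the plan size, since
    mutation-involving categories draw one member per pair from the mutated
    positions.
    """
    rng = np.random.default_rng(seed)
    if n_mutations is None:
        n_mutations = min(n_residues // 3, max(8, n_pairs // 10))
    base = n_pairs // 6
    counts = {c: base for c in _CATEGORY_ORDER}
    for c in rng.choice(list(_CATEGORY_ORDER), size=n_pairs - 6 * base, replace=False):
        counts[str(c)] += 1
    return FixturePlan(
        n_residues=n_residues,
        mutations=n_mutations,
        category_counts=counts,
        seed=int(seed),
        **overrides,
    )
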