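"""Read, clean, renumber and serialize PDB structures; detect mutations.

Cleaning follows the conventions of structure-preparation pipelines for
protein design: waters, ions and other heteroatom records are removed, only
the first coordinate model is kept, alternate locations are collapsed to the
highest-occupancy conformer, and residues are renumbered so that the first
residue in the file is at position 1.  The renumbered index is the single
authoritative residue coordinate used by every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import protein_letters_3to1

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Mutation",
    "PDBFormatError",
    "EmptyStructureError",
    "NonStandardResidueError",
    "UnmappedResidueError",
    "SequenceLengthMismatchError",
    "clean_structure",
    "write_pdb",
    "extract_sequence",
    "detect_mutations",
]

#: The 20 canonical three-letter amino-acid codes accepted after cleaning.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_1TO3 = {v: k for k, v in _3TO1.items() if k in STANDARD_RESIDUES}


class PDBFormatError(ValueError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class EmptyStructureError(ValueError):
    """No standard amino-acid ATOM records remain after cleaning."""


class NonStandardResidueError(ValueError):
    """An ATOM record names a non-canonical residue type (e.g. MSE)."""


class UnmappedResidueError(ValueError):
    """A three-letter residue code has no one-letter equivalent."""


class SequenceLengthMismatchError(ValueError):
    """Mutation detection requires equal-length sequences."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class Residue:
    """One amino-acid residue with its atoms.

    ``author_seq_id`` is the residue number as read from the file;
    ``renumbered_id`` is the contiguous 1-based index assigned by cleaning.
    """

    chain_id: str
    author_seq_id: int
    renumbered_id: int
    restype3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Mutation:
    """A substitution at a renumbered position, one-letter codes."""

    position: int
    ref_restype: str
    mut_restype: str

    def __post_init__(self):
        if self.ref_restype == self.mut_restype:
            raise ValueError(
                f"mutation at position {self.position} has identical "
                f"reference and mutant residue types ({self.ref_restype})"
            )

    def __str__(self) -> str:
        return f"{self.ref_restype}{self.position}{self.mut_restype}"


def _guess_element(atom_name: str) -> str:
    """Infer the element from an atom name when columns 77-78 are blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in ("H", "D"):
        return "H"
    # two-letter elements in proteins are rare; single leading letter suffices
    return stripped[0].upper()


def clean_structure(raw_pdb_text: str, source_label: str = "") -> Structure:
    """Parse PDB text into a cleaned, renumbered :class:`Structure`.

    Keeps polypeptide ATOM records of the first model only.  HETATM records
    (waters, ions, ligands) are discarded.  Alternate locations collapse to
    the highest-occupancy atom (ties: first listed).  Residues are renumbered
    1..N in file order across all chains; insertion codes are dropped.
    Hydrogens, when present, are retained.

    Raises
    ------
    EmptyStructureError
        if no standard amino-acid ATOM record is found.
    NonStandardResidueError
        if an ATOM record names a non-canonical residue type.
    PDBFormatError
        if a record's fixed-width fields cannot be parsed (reports the line).
    """
    residues: list[Residue] = []
    # residue key -> Residue; atom selection state per (residue key, atom name)
    res_by_key: dict[tuple, Residue] = {}
    best_occ: dict[tuple, float] = {}
    atom_slot: dict[tuple, int] = {}  # index into residue.atoms

    in_first_model = True
    seen_model = False

    for lineno, line in enumerate(raw_pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if seen_model:
                in_first_model = False
            seen_model = True
            continue
        if rec == "ENDMDL":
            in_first_model = False
            continue
        if rec != "ATOM" or not in_first_model:
            continue

        if len(line) < 54:
            raise PDBFormatError("ATOM record shorter than coordinate fields", lineno)
        atom_name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain_id = line[21]
        try:
            resseq = int(line[22:26])
        except ValueError:
            raise PDBFormatError(f"unparsable residue number {line[22:26]!r}", lineno)
        icode = line[26]
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError:
            raise PDBFormatError("unparsable coordinates", lineno)
        try:
            occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
        except ValueError:
            raise PDBFormatError(f"unparsable occupancy {line[54:60]!r}", lineno)
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(atom_name)

        if resname not in STANDARD_RESIDUES:
            raise NonStandardResidueError(
                f"non-standard residue {resname!r} at line {lineno}; "
                "only the 20 canonical amino acids are supported"
            )

        res_key = (chain_id, resseq, icode)
        if res_key not in res_by_key:
            residue = Residue(
                chain_id=chain_id,
                author_seq_id=resseq,
                renumbered_id=len(residues) + 1,
                restype3=resname,
            )
            res_by_key[res_key] = residue
            residues.append(residue)
        residue = res_by_key[res_key]

        atom = Atom(name=atom_name, element=element, x=x, y=y, z=z)
        akey = (res_key, atom_name)
        if altloc.strip() and akey in atom_slot:
            # alternate location of an atom already seen: keep higher occupancy
            if occupancy > best_occ[akey]:
                residue.atoms[atom_slot[akey]] = atom
                best_occ[akey] = occupancy
            continue
        atom_slot[akey] = len(residue.atoms)
        best_occ[akey] = occupancy
        residue.atoms.append(atom)

    if not residues:
        raise EmptyStructureError(
            "no standard amino-acid ATOM records found in input"
        )
    return Structure(residues=residues, source_label=source_label)


def write_pdb(s: Structure) -> str:
    """Serialize a cleaned structure as fixed-width PDB text (ATOM records only).

    Residues are written with their renumbered ids, so cleaning the output
    again is a no-op.
    """
    lines = []
    serial = 0
    prev_chain = None
    for res in s.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for atom in res.atoms:
            serial += 1
            name = atom.name
            # standard alignment: 1-3 char names start in column 14
            fname = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {fname:<4s} {res.restype3:>3s} "
                f"{res.chain_id}{res.renumbered_id:4d}    "
                f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_sequence(s: Structure) -> str:
    """One-letter sequence of a cleaned structure, in renumbered order."""
    if not s.residues:
        raise EmptyStructureError("cannot extract a sequence from an empty structure")
    letters = []
    for res in s.residues:
        try:
            letters.append(_3TO1[res.restype3])
        except KeyError:
            raise UnmappedResidueError(
                f"residue type {res.restype3!r} has no one-letter code"
            )
    return "".join(letters)


def one_to_three(letter: str) -> str:
    """Map a one-letter amino-acid code to its three-letter code."""
    try:
        return _1TO3[letter.upper()]
    except KeyError:
        raise UnmappedResidueError(f"unknown one-letter code {letter!r}")


def three_to_one(code3: str) -> str:
    """Map a canonical three-letter amino-acid code to one letter."""
    try:
        return _3TO1[code3.upper()]
    except KeyError:
        raise UnmappedResidueError(f"unknown three-letter code {code3!r}")


def detect_mutations(ref_seq: str, mut_seq: str) -> list[Mutation]:
    """List substitutions between two equal-length sequences.

    Positions are 1-based (the renumbered coordinate system).  Sequences of
    unequal length are rejected: the intended comparison is a design against
    its template, which shares length; indel alignment is out of scope.
    """
    if not ref_seq or not mut_seq:
        raise SequenceLengthMismatchError("sequences must be non-empty")
    if len(ref_seq) != len(mut_seq):
        raise SequenceLengthMismatchError(
            f"sequence lengths differ: reference {len(ref_seq)}, "
            f"mutant {len(mut_seq)}"
        )
    return [
        Mutation(position=i, ref_restype=a, mut_restype=b)
        for i, (a, b) in enumerate(zip(ref_seq, mut_seq), start=1)
        if a != b
    ]
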