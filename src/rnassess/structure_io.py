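"""Reading and writing PDB-format RNA coordinates.

The in-memory model (:class:`StructureModel`) is deliberately small: ordered
chains of ordered residues of named atoms, with everything the assessment
metrics need (coordinates, occupancies, element symbols) and nothing they do
not (no crystallographic metadata, no symmetry).

Parsing policy, applied record by record:

* only the first ``MODEL`` block is read unless another index is requested;
* alternate locations are resolved per atom name to the highest occupancy,
  ties going to the first altloc encountered;
* ``HETATM`` nucleotides (modified bases such as pseudouridine) are retained
  and mapped to their parent base; waters and free ions are always dropped;
  other ligands are dropped by default with an opt-in switch;
* primed atom names written with ``*`` (old PDB dialect, e.g. ``O3*``) are
  normalised to the ``'`` form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ParsePolicy",
    "PdbParseError",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "sequences_to_fasta",
]

#: Residue names accepted as standard ribonucleotides.
STANDARD_BASES = {"A": "A", "C": "C", "G": "G", "U": "U"}

#: Modified-nucleotide codes mapped to their parent base.  Extensible through
#: :attr:`ParsePolicy.modified_bases`.
MODIFIED_BASES = {
    "PSU": "U",   # pseudouridine
    "H2U": "U",   # dihydrouridine
    "4SU": "U",   # 4-thiouridine
    "5MU": "U",   # ribothymidine
    "5MC": "C",   # 5-methylcytidine
    "OMC": "C",   # 2'-O-methylcytidine
    "OMG": "G",   # 2'-O-methylguanosine
    "1MG": "G",
    "2MG": "G",
    "M2G": "G",
    "7MG": "G",
    "YG": "G",    # wybutosine
    "1MA": "A",
    "MIA": "A",
    "6MZ": "A",
    "I": "G",     # inosine pairs through its G-like WC face
}

#: Residue names dropped as solvent / free ions under every policy.
SOLVENT_NAMES = {"HOH", "WAT", "DOD"}
ION_NAMES = {"MG", "NA", "K", "CL", "ZN", "MN", "CA", "SR", "CS", "BR", "IOD", "NH4", "SO4", "PO4"}


class PdbParseError(ValueError):
    """Raised when a PDB record cannot be interpreted; names the line."""


@dataclass
class Atom:
    """A single atom: PDB-convention name, element, position in A."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    serial: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be nonempty")


@dataclass
class Residue:
    """One nucleotide (or retained ligand) with its atoms.

    ``base_type`` is the parent base letter (A/C/G/U) for nucleotides and
    ``None`` for retained non-nucleotide ligands.
    """

    chain_id: str
    number: int
    base_type: str | None
    res_name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        """Hashable identifier ``(chain_id, number, insertion_code)``."""
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def is_nucleotide(self) -> bool:
        return self.base_type is not None

    @property
    def is_purine(self) -> bool:
        return self.base_type in ("A", "G")

    @property
    def glycosidic_nitrogen(self) -> str:
        return "N9" if self.is_purine else "N1"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names=None) -> np.ndarray:
        """Stacked positions of ``names`` (all atoms when omitted)."""
        atoms = self.atoms if names is None else [self.atom(n) for n in names]
        return np.array([a.position for a in atoms if a is not None], dtype=float)


@dataclass
class StructureModel:
    """Ordered chains of residues; the unit every metric compares."""

    label: str
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    has_hydrogens: bool = False

    @property
    def residues(self) -> list[Residue]:
        return [r for _, res in self.chains for r in res]

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, res in self.chains:
            if cid == chain_id:
                return res
        raise KeyError(f"no chain {chain_id!r} in {self.label!r}")

    def residue(self, key: tuple[str, int, str]) -> Residue:
        for r in self.chain(key[0]):
            if r.key == key:
                return r
        raise KeyError(f"no residue {key} in {self.label!r}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        chains = []
        for cid, residues in self.chains:
            new = []
            for r in residues:
                atoms = [replace(a, position=R @ a.position + t) for a in r.atoms]
                new.append(replace(r, atoms=atoms))
            chains.append((cid, new))
        return StructureModel(self.label, chains, list(self.ligands), self.has_hydrogens)


@dataclass
class ParsePolicy:
    """Switches controlling :func:`read_pdb`."""

    model_index: int = 0          # which MODEL block (0-based) to keep
    keep_ligands: bool = False    # retain non-nucleotide HETATM groups
    modified_bases: dict | None = None  # extra code -> parent-base entries


def _normalise_atom_name(raw: str) -> str:
    """``O3*`` -> ``O3'`` (old dialect primes) and strip padding."""
    return raw.strip().replace("*", "'")


def _element_of(line: str, name: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem.capitalize()
    # fall back to the atom name: first alphabetic character
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_pdb(source, policy: ParsePolicy | None = None, label: str = "") -> StructureModel:
    """Parse PDB-dialect text into a :class:`StructureModel`.

    ``source`` may be a text stream, a string of PDB text, or a path.
    Raises :class:`PdbParseError` naming the line number on a malformed
    ATOM/HETATM record, and when no nucleotide residue survives the policy
    ("no RNA content").
    """
    policy = policy or ParsePolicy()
    if isinstance(source, str):
        if "\n" in source or source.lstrip()[:6] in ("ATOM", "ATOM  ", "HETATM", "MODEL"):
            stream = io.StringIO(source)
        else:
            stream = open(source)
    elif hasattr(source, "read"):
        stream = source
    else:  # pathlib.Path
        stream = open(source)

    base_map = dict(MODIFIED_BASES)
    if policy.modified_bases:
        base_map.update(policy.modified_bases)

    # residue accumulator: key -> (res_name, hetatm, {atom_name: [(occ, Atom)]})
    order: list[tuple] = []
    groups: dict[tuple, dict] = {}
    model_count = 0
    in_wanted_model = policy.model_index == 0
    saw_hydrogen = False

    for lineno, line in enumerate(stream, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if model_count == policy.model_index:
                in_wanted_model = True
            model_count += 1
            continue
        if rec == "ENDMDL":
            if in_wanted_model:
                in_wanted_model = model_count - 1 == policy.model_index
                if model_count > policy.model_index:
                    break
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if not in_wanted_model:
            continue
        try:
            name = _normalise_atom_name(line[12:16])
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or "A"
            res_num = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
            bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            serial = int(line[6:11]) if line[6:11].strip() else 0
        except (ValueError, IndexError) as exc:
            raise PdbParseError(f"unparseable {rec.strip()} record at line {lineno}: {exc}") from exc
        element = _element_of(line, name)
        if element == "H" or element == "D":
            saw_hydrogen = True
        key = (chain_id, res_num, icode)
        if key not in groups:
            order.append(key)
            groups[key] = {"res_name": res_name, "het": rec == "HETATM", "atoms": {}}
        atom = Atom(name, element, (x, y, z), occ, bfac, serial)
        groups[key]["atoms"].setdefault(name, []).append((altloc, occ, atom))

    if hasattr(stream, "close") and stream is not source:
        stream.close()

    chains: dict[str, list[Residue]] = {}
    chain_order: list[str] = []
    ligands: list[Residue] = []
    for key in order:
        g = groups[key]
        res_name = g["res_name"]
        # resolve altlocs: highest occupancy, tie -> first encountered
        atoms = []
        for name, cands in g["atoms"].items():
            best = max(cands, key=lambda c: c[1])  # max is stable: first of ties
            atoms.append(best[2])
        if res_name in SOLVENT_NAMES or res_name in ION_NAMES:
            continue
        if res_name in STANDARD_BASES:
            base = STANDARD_BASES[res_name]
        elif res_name in base_map:
            base = base_map[res_name]
        elif g["het"]:
            if policy.keep_ligands:
                ligands.append(Residue(key[0], key[1], None, res_name, key[2], atoms))
            continue
        else:
            raise PdbParseError(
                f"residue {res_name!r} at {key[0]}{key[1]}{key[2]} is not a known "
                f"nucleotide code; extend ParsePolicy.modified_bases to map it"
            )
        if key[0] not in chains:
            chains[key[0]] = []
            chain_order.append(key[0])
        chains[key[0]].append(Residue(key[0], key[1], base, res_name, key[2], atoms))

    for cid in chain_order:
        chains[cid].sort(key=lambda r: (r.number, r.insertion_code))

    model = StructureModel(
        label=label,
        chains=[(cid, chains[cid]) for cid in chain_order],
        ligands=ligands,
        has_hydrogens=saw_hydrogen,
    )
    if not model.residues:
        raise PdbParseError("no RNA content")
    return model


def write_pdb(model: StructureModel, sink=None) -> str | None:
    """Emit standard fixed-width ATOM records (1-based serials, 3-decimal A).

    Returns the text when ``sink`` is ``None``, otherwise writes to the
    stream or path.  Round-trips through :func:`read_pdb` reproduce
    coordinates exactly at the written precision.
    """
    if not model.residues:
        raise ValueError("cannot write an empty model")
    lines = []
    serial = 0
    for cid, residues in model.chains:
        for r in residues:
            for a in r.atoms:
                serial += 1
                lines.append(_format_atom(a, r, serial))
        serial += 1
        last = residues[-1]
        lines.append(
            f"TER   {serial:5d}      {last.res_name:>3s} {cid:1s}{last.number:4d}"
            f"{last.insertion_code or ' ':1s}"
        )
    for r in model.ligands:
        for a in r.atoms:
            serial += 1
            lines.append(_format_atom(a, r, serial, het=True))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if sink is None:
        return text
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)
    return None


def _format_atom(a: Atom, r: Residue, serial: int, het: bool = False) -> str:
    if len(a.name) > 4:
        raise ValueError(f"atom name {a.name!r} exceeds the 4-character PDB field")
    # PDB alignment rule: 1-2 character element symbols start in column 13;
    # names of atoms with 1-letter elements are indented one space.
    if len(a.name) < 4 and len(a.element) == 1:
        name_field = f" {a.name:<3s}"
    else:
        name_field = f"{a.name:<4s}"
    rec = "HETATM" if het else "ATOM  "
    x, y, z = a.position
    return (
        f"{rec}{serial:5d} {name_field}{'':1s}{r.res_name:>3s} {r.chain_id:1s}"
        f"{r.number:4d}{r.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element:>2s}"
    )


def extract_sequence(model: StructureModel) -> dict[str, str]:
    """Per-chain nucleotide strings, modified bases mapped to parent letters."""
    out = {}
    for cid, residues in model.chains:
        letters = []
        for r in residues:
            if r.base_type is None:
                raise ValueError(f"residue {r.res_name!r} at {r.key} has no parent base")
            letters.append(r.base_type)
        out[cid] = "".join(letters)
    return out


def sequences_to_fasta(model: StructureModel) -> str:
    """Chain sequences in FASTA, one record per chain."""
    seqs = extract_sequence(model)
    parts = []
    for cid, seq in seqs.items():
        parts.append(f">{model.label or 'model'}|chain_{cid}")
        parts.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(parts) + "\n"
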