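"""Domain model for protein complexes plus PDB/mmCIF readers and writers.

The unit every pipeline stage operates on is :class:`ComplexStructure`:
chains of ordered residues of atoms with coordinates in Angstroms.  Author
residue numbering (number + insertion code) is preserved verbatim from the
source file; any internal positional indexing is 0-based and explicit.

Sequences are derived from the resolved (coordinate) residues, not from
SEQRES, because downstream alignment must map onto residues that physically
exist for superposition and mutation placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "ComplexStructure",
    "SubunitDefinition",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "three_to_one",
]

#: canonical 3-letter -> 1-letter amino-acid codes
_CANONICAL = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: common modified residues mapped to their parent 1-letter code
_MODIFIED = {
    "MSE": "M",  # selenomethionine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "CSO": "C",  # S-hydroxycysteine
    "CME": "C",
    "KCX": "K",
    "MLY": "K",
    "HYP": "P",  # hydroxyproline
    "PCA": "Q",  # pyroglutamate
    "FME": "M",
}

_WATER = {"HOH", "WAT", "DOD"}


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue name to a 1-letter code; unknown -> 'X'."""
    resname = resname.strip().upper()
    return _CANONICAL.get(resname) or _MODIFIED.get(resname, "X")


@dataclass
class AtomRecord:
    """A single atom: label, element, Cartesian position in Angstroms."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstroms
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue with author numbering (number + insertion code)."""

    number: int
    icode: str
    resname: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_canonical: bool = True

    @property
    def one_letter(self) -> str:
        return three_to_one(self.resname)

    @property
    def label(self) -> str:
        """Author-number label, e.g. ``52`` or ``52A``."""
        return f"{self.number}{self.icode}".strip()

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for r in self.residues:
            key = (r.number, r.icode)
            if key in seen:
                raise ValueError(
                    f"chain {self.chain_id}: duplicate residue {r.label}"
                )
            seen.add(key)

    @property
    def sequence(self) -> str:
        """1-letter sequence over resolved residues, in file order."""
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ComplexStructure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"{self.structure_id}: structure has no chains")
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.structure_id}: duplicate chain IDs {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"{self.structure_id}: no chain {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


@dataclass(frozen=True)
class SubunitDefinition:
    """Partition of the query's relevant chains into the two binding partners."""

    subunit1: tuple[str, ...]
    subunit2: tuple[str, ...]

    def __init__(self, subunit1: Iterable[str], subunit2: Iterable[str]):
        object.__setattr__(self, "subunit1", tuple(subunit1))
        object.__setattr__(self, "subunit2", tuple(subunit2))
        if not self.subunit1 or not self.subunit2:
            raise ValueError("both subunits must contain at least one chain")
        if set(self.subunit1) & set(self.subunit2):
            raise ValueError("subunits must be disjoint")

    @property
    def all_chains(self) -> tuple[str, ...]:
        return self.subunit1 + self.subunit2

    def side_of(self, chain_id: str) -> int:
        """1 or 2 for member chains; raises for others."""
        if chain_id in self.subunit1:
            return 1
        if chain_id in self.subunit2:
            return 2
        raise KeyError(f"chain {chain_id!r} is in neither subunit")

    def validate_against(self, complex_: ComplexStructure) -> None:
        missing = [c for c in self.all_chains if c not in complex_.chain_ids]
        if missing:
            raise ValueError(
                f"subunit chains {missing} not present in {complex_.structure_id}"
            )

    def key(self) -> str:
        return ",".join(self.subunit1) + "|" + ",".join(self.subunit2)


# ---------------------------------------------------------------------------
# I/O via gemmi
# ---------------------------------------------------------------------------

Format = Literal["pdb", "mmcif", "auto"]


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    # sniff: mmCIF files start with 'data_'
    with open(path, "r", errors="replace") as fh:
        head = fh.read(64)
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, tie -> altloc 'A'."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
        out.append(best)
    return out


def read_structure(path: str | Path, format: Format = "auto") -> ComplexStructure:
    """Read a complex from a PDB or mmCIF file.

    Only model 1 is kept; waters are dropped; alternate locations are
    collapsed to the highest-occupancy conformer (ties prefer altloc 'A');
    HETATM residues are retained but flagged non-canonical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    try:
        if fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    model = st[0]  # model 1 only

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            resname = gres.name.strip().upper()
            if resname in _WATER:
                continue
            atoms = [
                AtomRecord(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    altloc=(ga.altloc if ga.altloc != "\x00" else "").strip(),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                )
                for ga in gres
            ]
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            residues.append(
                Residue(
                    number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    resname=resname,
                    atoms=atoms,
                    is_canonical=resname in _CANONICAL,
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise ValueError(f"{path}: structure contains no (non-water) residues")
    return ComplexStructure(
        structure_id=path.stem, chains=chains, source_path=str(path)
    )


def _to_gemmi(complex_: ComplexStructure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = complex_.structure_id
    model = gemmi.Model(1)
    for chain in complex_.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.resname
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "A" if res.is_canonical else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.altloc = "\x00"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(
    complex_: ComplexStructure, path: str | Path, format: Format = "auto"
) -> Path:
    """Write a complex to PDB or mmCIF; ``read_structure`` inverts it."""
    path = Path(path)
    fmt = _detect_format_for_write(path) if format == "auto" else format
    if fmt == "pdb":
        too_long = [c.chain_id for c in complex_.chains if len(c.chain_id) > 1]
        if too_long:
            raise ValueError(
                f"chain IDs {too_long} exceed the single-character PDB limit; "
                "use mmCIF"
            )
    st = _to_gemmi(complex_)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def _detect_format_for_write(path: Path) -> str:
    return "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"


def extract_sequence(chain: Chain) -> str:
    """1-letter sequence of a chain's resolved residues ('X' for unknowns)."""
    if not chain.residues:
        raise ValueError(f"chain {chain.chain_id} is empty")
    return chain.sequence


def transform_structure(
    complex_: ComplexStructure, rotation: np.ndarray, translation: np.ndarray
) -> ComplexStructure:
    """Return a copy with every atom moved by ``x -> R x + t``."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    new_chains = []
    for chain in complex_.chains:
        new_residues = []
        for res in chain.residues:
            new_atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element,
                    position=rotation @ a.position + translation,
                    altloc=a.altloc,
                    occupancy=a.occupancy,
                )
                for a in res.atoms
            ]
            new_residues.append(
                Residue(res.number, res.icode, res.resname, new_atoms, res.is_canonical)
            )
        new_chains.append(Chain(chain.chain_id, new_residues))
    return ComplexStructure(
        structure_id=complex_.structure_id,
        chains=new_chains,
        source_path=complex_.source_path,
    )
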