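"""PDB input/output and the two-point (Cα, fa) residue reduction.

Each residue is reduced to its alpha carbon and the side-chain heavy atom
furthest from it (*fa*).  This two-point representation, labelled with the
residue type, is all the matching engine ever sees of a structure.

Parsing is delegated to Bio.PDB (strict construction, so malformed coordinate
fields raise an error naming the offending line); only the first MODEL is
read, HETATM/waters/hydrogens/non-standard residues are dropped, and for
alternate locations the highest-occupancy conformer is kept (ties resolved to
the first in file order).
"""

from __future__ import annotations

import copy
import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.PDB.Polypeptide import is_aa, protein_letters_3to1

from .errors import LookupFailure, ParseError, UnsupportedMutation

log = logging.getLogger(__name__)

#: Backbone atoms never eligible as fa.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Three-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = frozenset(k for k in protein_letters_3to1 if len(k) == 3)

#: One-letter → three-letter for convenience in annotations and fixtures.
ONE_TO_THREE = {v: k for k, v in protein_letters_3to1.items() if len(k) == 3}


class Identity(NamedTuple):
    """Residue identity: (chain, seq_number, insertion_code, res_type)."""

    chain: str
    seq_number: int
    insertion_code: str
    res_type: str


@dataclass(frozen=True, eq=False)
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class ResidueRecord:
    chain: str
    seq_number: int
    insertion_code: str
    res_type: str  # three-letter code
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_number, self.insertion_code)

    @property
    def identity(self) -> Identity:
        return Identity(self.chain, self.seq_number, self.insertion_code, self.res_type)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True, eq=False)
class ResiduePoint:
    """A residue reduced to Cα plus furthest side-chain heavy atom.

    ``fa`` is None exactly when the file contains no side-chain heavy atom for
    the residue (truncated side chain); glycine, which has none by chemistry,
    instead carries ``fa == ca`` so the distance matrices stay well defined.
    """

    identity: Identity
    ca: np.ndarray
    fa: np.ndarray | None
    fa_atom_name: str | None

    @property
    def has_fa(self) -> bool:
        return self.fa is not None


@dataclass
class StructureModel:
    structure_id: str
    residues: list[ResidueRecord]

    def find(self, chain: str, seq_number: int, insertion_code: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.key == (chain, seq_number, insertion_code):
                return r
        return None


def parse_pdb(text: str, structure_id: str = "query") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is read.  HETATM records, waters, hydrogens and
    non-standard residues are excluded.  Alternate locations resolve to the
    highest-occupancy conformer (first in file on ties).
    """
    if not any(line.startswith("ATOM") for line in text.splitlines()):
        raise ParseError("input contains no ATOM records")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(structure_id, io.StringIO(text))
    except PDBConstructionException as exc:
        raise ParseError(f"malformed PDB record: {exc}") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - ATOM check above precludes this
        raise ParseError("input contains no coordinate model")

    residues: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag != " " or not is_aa(res, standard=True):
                continue
            atoms = []
            for atom in res:  # disordered atoms yield the selected altloc
                if atom.element in ("H", "D"):
                    continue
                atoms.append(
                    AtomRecord(
                        name=atom.get_name(),
                        element=atom.element,
                        coords=np.array(atom.get_coord(), dtype=float),
                        altloc=atom.get_altloc().strip(),
                        occupancy=float(min(max(atom.get_occupancy() or 1.0, 0.0), 1.0)),
                    )
                )
            residues.append(
                ResidueRecord(
                    chain=chain.id,
                    seq_number=int(resseq),
                    insertion_code=icode.strip(),
                    res_type=res.get_resname(),
                    atoms=atoms,
                )
            )
    if not residues:
        raise ParseError("no standard amino-acid ATOM records found")
    return StructureModel(structure_id=structure_id, residues=residues)


def read_pdb(path, structure_id: str | None = None) -> StructureModel:
    with open(path) as fh:
        text = fh.read()
    sid = structure_id or _stem(path)
    return parse_pdb(text, structure_id=sid)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


_ATOM_FMT = (
    "ATOM  {serial:5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}{seq:4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def write_pdb(model: StructureModel) -> str:
    """Render a StructureModel as PDB ATOM records (3-decimal coordinates)."""
    out, serial = [], 1
    for r in model.residues:
        for a in r.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name}"
            out.append(
                _ATOM_FMT.format(
                    serial=serial,
                    name=name,
                    altloc=a.altloc or " ",
                    res=r.res_type,
                    chain=r.chain or "A",
                    seq=r.seq_number,
                    icode=r.insertion_code or " ",
                    x=a.coords[0],
                    y=a.coords[1],
                    z=a.coords[2],
                    occ=a.occupancy,
                    b=0.0,
                    elem=a.element,
                )
            )
            serial += 1
    out.append("END\n")
    return "".join(out)


def derive_residue_points(model: StructureModel) -> list[ResiduePoint]:
    """Reduce every residue to (Cα, fa).

    fa is the side-chain heavy atom maximising the Euclidean distance to Cα
    (ties broken by lexicographically smallest atom name).  Glycine gets
    fa := Cα.  A non-glycine residue whose side-chain atoms are all missing
    from the file gets fa = None.  Residues without a Cα are dropped with a
    logged warning.
    """
    points = []
    for r in model.residues:
        ca = r.atom("CA")
        if ca is None:
            log.warning("residue %s %s%d%s has no CA atom; dropped",
                        r.res_type, r.chain, r.seq_number, r.insertion_code)
            continue
        if r.res_type == "GLY":
            points.append(ResiduePoint(r.identity, ca.coords, ca.coords.copy(), "CA"))
            continue
        side = [a for a in r.atoms if a.name not in BACKBONE_ATOMS]
        if not side:
            points.append(ResiduePoint(r.identity, ca.coords, None, None))
            continue
        best = min(side, key=lambda a: (-float(np.linalg.norm(a.coords - ca.coords)), a.name))
        points.append(ResiduePoint(r.identity, ca.coords, best.coords, best.name))
    return points


def mutate_to_alanine(model: StructureModel, chain: str, seq_number: int,
                      insertion_code: str = "") -> StructureModel:
    """Return a copy of *model* with one residue substituted by alanine.

    The side chain is truncated at Cβ, mimicking in-silico alanine scanning.
    GLY and ALA targets, and residues lacking a CB atom, are rejected.
    """
    target = model.find(chain, seq_number, insertion_code)
    if target is None:
        raise LookupFailure(f"residue {chain}{seq_number}{insertion_code} not found in "
                            f"{model.structure_id}")
    if target.res_type in ("GLY", "ALA"):
        raise UnsupportedMutation(f"cannot alanine-substitute {target.res_type} "
                                  f"{chain}{seq_number}{insertion_code}")
    if target.atom("CB") is None:
        raise UnsupportedMutation(f"residue {chain}{seq_number}{insertion_code} has no CB atom")
    mutated = copy.deepcopy(model)
    res = mutated.find(chain, seq_number, insertion_code)
    res.res_type = "ALA"
    res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS or a.name == "CB"]
    return mutated


def read_sites_tsv(path):
    """Read the catalytic-site annotation table.

    Required columns: structure_id, chain, seq_number, icode, res_type
    (three-letter).  Optional: family_id (defaults to structure_id),
    ec_number (defaults to empty).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["structure_id", "chain", "seq_number", "icode", "res_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"sites table {path} missing columns: {missing}")
    if "family_id" not in df.columns:
        df["family_id"] = df["structure_id"]
    if "ec_number" not in df.columns:
        df["ec_number"] = ""
    df["seq_number"] = df["seq_number"].astype(int)
    return df
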