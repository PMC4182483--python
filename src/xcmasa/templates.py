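"""Active-site templates: construction, master-template selection, and the
n−1 subtemplate library extension.

A template t_i is the ordered set of (Cα, fa) coordinates of the n_ti
catalytic residues of one annotated enzyme.  For a family of comparable
templates the *master template* is the member minimising the mean RMSD to all
members.  The extended library adds, for every template, the n_ti
subtemplates obtained by omitting one residue each, so that a site with one
mutated residue or one unrepresentable fa atom can still be recovered through
its non-mutated remainder.  For N_T templates of at most n_max residues this
adds at most N_T × n_max entries.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (AnnotationConflict, FormatError, IncomparableTemplates,
                     IncompleteSite, ValidationError)
from .statistics import superpose_rmsd
from .structure_io import (ONE_TO_THREE, Identity, ResiduePoint, StructureModel,
                           derive_residue_points, protein_letters_3to1)

log = logging.getLogger(__name__)

LIBRARY_FORMAT = "xcmasa-library"
LIBRARY_VERSION = 1


@dataclass(frozen=True)
class Template:
    template_id: str
    source_structure: str
    family_id: str
    residues: tuple  # of ResiduePoint, ordered, every fa present
    ec_number: str = ""
    parent_template: str | None = None
    excluded_residues: tuple = ()  # identities omitted relative to the parent

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValidationError(f"template {self.template_id}: needs ≥2 residues")
        if any(r.fa is None for r in self.residues):
            raise ValidationError(f"template {self.template_id}: every residue needs fa")
        if (self.parent_template is None) != (len(self.excluded_residues) == 0):
            raise ValidationError(f"template {self.template_id}: excluded_residues must be "
                                  "set iff parent_template is set")

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def is_subtemplate(self) -> bool:
        return self.parent_template is not None

    @property
    def res_types(self) -> tuple:
        """One-letter residue types, in template order."""
        return tuple(protein_letters_3to1[r.identity.res_type] for r in self.residues)

    def coords(self) -> np.ndarray:
        """(2n, 3) array: all Cα rows, then all fa rows."""
        return np.vstack([r.ca for r in self.residues] + [r.fa for r in self.residues])


@dataclass
class TemplateLibrary:
    templates: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [t.template_id for t in self.templates]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate template_ids in library")
        known = set(ids)
        for t in self.templates:
            if t.parent_template is not None and t.parent_template not in known:
                raise ValidationError(f"subtemplate {t.template_id}: parent "
                                      f"{t.parent_template} not in library")

    def __len__(self):
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def get(self, template_id: str):
        for t in self.templates:
            if t.template_id == template_id:
                return t
        return None


@dataclass
class FamilyGroup:
    family_id: str
    templates: list

    def __post_init__(self):
        if not self.templates:
            raise ValidationError(f"family {self.family_id} is empty")


def build_template(model: StructureModel, site_rows, template_id: str | None = None,
                   family_id: str | None = None, ec_number: str = "") -> Template:
    """Build a template from a structure and its catalytic-site annotation.

    *site_rows* is an iterable of (chain, seq_number, icode, res_type) with
    res_type a three-letter code.  Residues are ordered by
    (chain, seq_number, insertion_code); every one must be present with both
    Cα and fa.
    """
    points = {p.identity[:3]: p for p in derive_residue_points(model)}
    selected = []
    for chain, seq, icode, res_type in site_rows:
        key = (str(chain), int(seq), str(icode or ""))
        p = points.get(key)
        if p is None:
            raise IncompleteSite(f"{model.structure_id}: annotated residue "
                                 f"{key[0]}{key[1]}{key[2]} absent or has no CA")
        if p.fa is None:
            raise IncompleteSite(f"{model.structure_id}: residue {key[0]}{key[1]}{key[2]} "
                                 "has no side-chain heavy atom (fa absent)")
        if p.identity.res_type != res_type:
            raise AnnotationConflict(f"{model.structure_id}: residue {key[0]}{key[1]} is "
                                     f"{p.identity.res_type}, annotation says {res_type}")
        selected.append(p)
    if len(selected) < 2:
        raise ValidationError(f"{model.structure_id}: a template needs ≥2 residues")
    selected.sort(key=lambda p: (p.identity.chain, p.identity.seq_number,
                                 p.identity.insertion_code))
    return Template(
        template_id=template_id or model.structure_id,
        source_structure=model.structure_id,
        family_id=family_id or model.structure_id,
        ec_number=ec_number,
        residues=tuple(selected),
    )


def template_rmsd(a: Template, b: Template) -> float:
    """Least-squares rigid-superposition RMSD over the 2n (Cα then fa) points."""
    if a.n != b.n or a.res_types != b.res_types:
        raise IncomparableTemplates(
            f"{a.template_id} ({a.n}:{''.join(a.res_types)}) vs "
            f"{b.template_id} ({b.n}:{''.join(b.res_types)})")
    return superpose_rmsd(a.coords(), b.coords())


def select_master_template(fam: FamilyGroup) -> Template:
    """Pick the family member minimising the mean RMSD to all members.

    Members not mutually comparable with the majority signature (size and
    residue-type sequence) are excluded with a warning; the i = j zero term is
    included in the mean.  Ties go to the lexicographically smallest id.
    """
    from collections import Counter

    sigs = Counter((t.n, t.res_types) for t in fam.templates)
    ref_sig = sigs.most_common(1)[0][0]
    members = [t for t in fam.templates if (t.n, t.res_types) == ref_sig]
    dropped = [t.template_id for t in fam.templates if (t.n, t.res_types) != ref_sig]
    if dropped:
        log.warning("family %s: excluding incomparable members %s", fam.family_id, dropped)
    n_r = len(members)
    scores = {t.template_id: sum(template_rmsd(t, u) for u in members) / n_r
              for t in members}
    floor = min(scores.values())
    best_id = min(tid for tid, s in scores.items() if s <= floor + 1e-9)
    return next(t for t in members if t.template_id == best_id)


def subtemplates(t: Template, k: int = 1, min_size: int = 2):
    """Yield all size n−k subtemplates of *t* (empty if n−k < min_size)."""
    if t.n - k < min_size:
        return
    for kept in itertools.combinations(range(t.n), t.n - k):
        excluded = tuple(t.residues[i].identity for i in range(t.n) if i not in kept)
        suffix = "+".join(f"{i.chain}{i.seq_number}{i.insertion_code}" for i in excluded)
        yield replace(
            t,
            template_id=f"{t.template_id}~minus-{suffix}",
            residues=tuple(t.residues[i] for i in kept),
            parent_template=t.template_id,
            excluded_residues=excluded,
        )


def expand_library(lib: TemplateLibrary, k: int = 1, min_size: int = 2) -> TemplateLibrary:
    """Extend the library with all n−k subtemplates of every template.

    With k = 1 (the single-point-mutation case) each template of size
    n_ti ≥ min_size + 1 contributes exactly n_ti subtemplates and the total
    addition is bounded by N_T × n_max.  Larger k grows combinatorially
    (binomial(n, k)) and is exponential as k approaches n/2.  Originals are
    retained; templates too small to expand pass through unchanged.
    """
    if k < 1 or min_size < 2:
        raise ValidationError("expand_library requires k ≥ 1 and min_size ≥ 2")
    out = list(lib.templates)
    for t in lib.templates:
        if t.is_subtemplate:
            continue
        out.extend(subtemplates(t, k=k, min_size=min_size))
    meta = dict(lib.metadata)
    meta.update({"k": k, "min_size": min_size, "expanded": True})
    return TemplateLibrary(templates=out, metadata=meta)


# ---------------------------------------------------------------------------
# Library serialisation: JSON-lines with a versioned header record.

def _point_to_json(p: ResiduePoint) -> dict:
    return {
        "identity": list(p.identity),
        "ca": [float(x) for x in p.ca],
        "fa": [float(x) for x in p.fa],
        "fa_atom_name": p.fa_atom_name,
    }


def _point_from_json(d: dict) -> ResiduePoint:
    ident = Identity(*d["identity"])
    return ResiduePoint(ident, np.array(d["ca"], dtype=float),
                        np.array(d["fa"], dtype=float), d["fa_atom_name"])


def write_library(lib: TemplateLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write(json.dumps({"format": LIBRARY_FORMAT, "version": LIBRARY_VERSION,
                             "metadata": lib.metadata}) + "\n")
        for t in lib.templates:
            fh.write(json.dumps({
                "template_id": t.template_id,
                "source_structure": t.source_structure,
                "family_id": t.family_id,
                "ec_number": t.ec_number,
                "parent_template": t.parent_template,
                "excluded_residues": [list(i) for i in t.excluded_residues],
                "residues": [_point_to_json(p) for p in t.residues],
            }) + "\n")


def read_library(path) -> TemplateLibrary:
    templates = []
    with open(path) as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: bad library header: {exc}") from exc
        if header.get("format") != LIBRARY_FORMAT:
            raise FormatError(f"{path}: not a template library file")
        if header.get("version") != LIBRARY_VERSION:
            raise FormatError(f"{path}: unsupported library version {header.get('version')}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
                templates.append(Template(
                    template_id=d["template_id"],
                    source_structure=d["source_structure"],
                    family_id=d["family_id"],
                    ec_number=d.get("ec_number", ""),
                    parent_template=d.get("parent_template"),
                    excluded_residues=tuple(Identity(*i) for i in d["excluded_residues"]),
                    residues=tuple(_point_from_json(p) for p in d["residues"]),
                ))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed template record: {exc}") from exc
    return TemplateLibrary(templates=templates, metadata=header.get("metadata", {}))
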