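"""Synthetic structures and benchmarks: decoy pseudo-proteins, planted
catalytic sites, point mutations and missing side-chain atoms.

Decoys are self-avoiding pseudo-chains with realistic Cα spacing (3.8 Å) and
plausible side-chain geometry, not physical models — sufficient because the
matching engine only ever sees residue types and the two-point (Cα, fa)
reduction.  A *positive* query is a decoy into which a template's site
geometry has been planted (optionally jittered); alanine scanning and
fa-atom deletion then emulate the mutated / missing-data test conditions.

All generators take an explicit seed and use numpy's PCG64 generator, so
identical inputs reproduce identical output bytes on any platform.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .evaluation import Label, LabeledQuery
from .statistics import load_abundance_table
from .structure_io import (ONE_TO_THREE, AtomRecord, Identity, ResiduePoint,
                           ResidueRecord, StructureModel, write_pdb)
from .templates import Template, TemplateLibrary

#: Representative distal side-chain heavy atom per residue type (name, element).
DISTAL_ATOM = {
    "R": ("NH1", "N"), "K": ("NZ", "N"), "E": ("OE1", "O"), "D": ("OD1", "O"),
    "Q": ("NE2", "N"), "N": ("ND2", "N"), "H": ("NE2", "N"), "F": ("CZ", "C"),
    "Y": ("OH", "O"), "W": ("CH2", "C"), "S": ("OG", "O"), "T": ("OG1", "O"),
    "C": ("SG", "S"), "M": ("CE", "C"), "L": ("CD1", "C"), "I": ("CD1", "C"),
    "V": ("CG1", "C"), "P": ("CG", "C"), "A": ("CB", "C"),
}

#: Types over-represented among catalytic residues; used for synthetic sites.
CATALYTIC_TYPES = "DEHKSTCRNY"

CB_LENGTH = 1.53  # Å, Cα–Cβ bond


def _unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _residue(chain, seq, one_letter, ca, fa_dir=None, fa_len=None, rng=None):
    """Build a two/three-atom ResidueRecord at the given Cα position."""
    atoms = [AtomRecord("CA", "C", ca)]
    if one_letter == "G":
        return ResidueRecord(chain, seq, "", "GLY", atoms)
    u = fa_dir if fa_dir is not None else _unit(rng)
    atoms.append(AtomRecord("CB", "C", ca + CB_LENGTH * u))
    if one_letter != "A":
        name, elem = DISTAL_ATOM[one_letter]
        length = fa_len if fa_len is not None else rng.uniform(2.4, 4.0)
        atoms.append(AtomRecord(name, elem, ca + length * u))
    return ResidueRecord(chain, seq, "", ONE_TO_THREE[one_letter], atoms)


def make_decoy(n: int, seed: int, structure_id: str | None = None) -> StructureModel:
    """A self-avoiding pseudo-chain of *n* residues with no planted site.

    Consecutive Cα spacing is 3.8 ± 0.1 Å; non-adjacent residues keep ≥ 4 Å
    apart; residue types are drawn from the background abundance table
    (glycine excluded so every residue carries a full two-point reduction).
    """
    if n < 5:
        raise ValidationError("decoys need at least 5 residues")
    rng = np.random.default_rng(seed)
    table = load_abundance_table()
    types = [t for t in sorted(table.freq) if t != "G"]
    probs = np.array([table.freq[t] for t in types])
    probs = probs / probs.sum()

    coords = [np.zeros(3)]
    while len(coords) < n:
        for _ in range(200):
            step = rng.uniform(3.7, 3.9) * _unit(rng)
            cand = coords[-1] + step
            clashes = [c for c in coords[:-1] if np.linalg.norm(cand - c) < 4.0]
            if not clashes:
                coords.append(cand)
                break
        else:  # trapped; back out one residue and retry
            coords.pop()
            if not coords:
                coords = [np.zeros(3)]

    residues = []
    for i, ca in enumerate(coords):
        t = types[int(rng.choice(len(types), p=probs))]
        residues.append(_residue("A", i + 1, t, ca, rng=rng))
    return StructureModel(structure_id or f"decoy{seed}", residues)


def plant_site(model: StructureModel, t: Template, jitter_sigma: float,
               seed: int):
    """Overwrite non-adjacent residues of *model* with the site geometry of *t*.

    The template is placed under a random rigid motion, iid Gaussian noise of
    σ = *jitter_sigma* is added to every Cα and fa position, the chosen
    residues are retyped, and the truth identities are returned alongside the
    modified copy.
    """
    import copy

    n = t.n
    if len(model.residues) < 3 * n:
        raise ValidationError("structure too small to plant the site in")
    rng = np.random.default_rng(seed)

    # non-adjacent residue slots, random but reproducible
    perm = rng.permutation(len(model.residues))
    slots: list[int] = []
    for idx in perm:
        if all(abs(int(idx) - s) > 1 for s in slots):
            slots.append(int(idx))
        if len(slots) == n:
            break
    slots.sort()

    # random rigid placement, shifted well clear of the decoy chain
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(size=3)
    shift = (np.max([np.linalg.norm(r.atoms[0].coords) for r in model.residues]) + 20.0) \
        * shift / np.linalg.norm(shift)

    planted = copy.deepcopy(model)
    truth = []
    for slot, (j, tres) in zip(slots, enumerate(t.residues)):
        old = planted.residues[slot]
        one = t.res_types[j]
        ca = rot @ tres.ca + shift + rng.normal(scale=jitter_sigma, size=3)
        fa = rot @ tres.fa + shift + rng.normal(scale=jitter_sigma, size=3)
        if one == "G":
            new = ResidueRecord(old.chain, old.seq_number, old.insertion_code, "GLY",
                                [AtomRecord("CA", "C", ca)])
        else:
            d = fa - ca
            norm = np.linalg.norm(d)
            u = d / norm if norm > 1e-9 else _unit(rng)
            atoms = [AtomRecord("CA", "C", ca),
                     AtomRecord("CB", "C", ca + CB_LENGTH * u)]
            name, elem = DISTAL_ATOM[one]
            if one != "A":
                atoms.append(AtomRecord(name, elem, fa))
            new = ResidueRecord(old.chain, old.seq_number, old.insertion_code,
                                ONE_TO_THREE[one], atoms)
        planted.residues[slot] = new
        truth.append(new.identity)
    return planted, tuple(truth)


def delete_side_chain(model: StructureModel, identity) -> StructureModel:
    """Remove all side-chain atoms of one residue (its fa becomes absent)."""
    import copy

    from .structure_io import BACKBONE_ATOMS

    out = copy.deepcopy(model)
    res = out.find(identity[0], identity[1], identity[2])
    if res is None:
        raise ValidationError(f"residue {identity} not found")
    res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    return out


def make_template(template_id: str, seed: int, site_size: int = 3,
                  family_id: str | None = None) -> Template:
    """One synthetic catalytic-site template with plausible geometry.

    Residue types are drawn from the catalytically common polar/charged
    types; Cα positions keep pairwise 4–12 Å; fa atoms sit 2.4–4 Å out.
    """
    rng = np.random.default_rng(seed)
    for _ in range(500):
        cas = rng.uniform(-6.0, 6.0, size=(site_size, 3))
        d = np.linalg.norm(cas[:, None] - cas[None, :], axis=-1)
        off = d[np.triu_indices(site_size, 1)]
        if np.all(off > 4.0) and np.all(off < 12.0):
            break
    else:  # pragma: no cover
        raise ValidationError("could not sample template geometry")
    residues = []
    for j in range(site_size):
        one = CATALYTIC_TYPES[int(rng.integers(len(CATALYTIC_TYPES)))]
        fa = cas[j] + rng.uniform(2.4, 4.0) * _unit(rng)
        ident = Identity("T", j + 1, "", ONE_TO_THREE[one])
        residues.append(ResiduePoint(ident, cas[j], fa, DISTAL_ATOM[one][0]))
    return Template(template_id=template_id, source_structure=template_id,
                    family_id=family_id or template_id, residues=tuple(residues))


def make_template_library(n_templates: int, seed: int, site_size: int = 3) -> TemplateLibrary:
    rng = np.random.default_rng(seed)
    templates = [make_template(f"synth-{i:02d}", int(rng.integers(2**31)),
                               site_size=site_size) for i in range(n_templates)]
    return TemplateLibrary(templates=templates,
                           metadata={"generator": "xcmasa.fixtures", "seed": seed,
                                     "site_size": site_size})


@dataclass
class FixtureSpec:
    """Recipe for a reproducible synthetic benchmark.

    With ``planted_template=None`` a library of ``n_templates`` random
    3-residue-site templates is generated and positives are planted
    round-robin from it.  ``mutation="alanine_scan"`` substitutes one random
    catalytic residue per positive by alanine; ``delete_fa_of`` removes the
    side chain of the truth residue at that index instead.
    """

    n_residues: int = 150
    n_positives: int = 20
    n_negatives: int = 100
    planted_template: Template | None = None
    n_templates: int = 20
    site_size: int = 3
    jitter_sigma: float = 0.0
    mutation: str = "none"  # "none" | "alanine_scan"
    delete_fa_of: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be ≥ 0")
        if self.mutation not in ("none", "alanine_scan"):
            raise ValidationError(f"unknown mutation scheme {self.mutation!r}")
        if min(self.n_positives, self.n_negatives) < 0 or self.n_residues < 15:
            raise ValidationError("benchmark sizes out of range")


def make_benchmark(spec: FixtureSpec):
    """Build labelled queries and the (unexpanded) master template library."""
    from .evaluation import alanine_scan_set

    rng = np.random.default_rng(spec.seed)
    if spec.planted_template is not None:
        lib = TemplateLibrary([spec.planted_template],
                              metadata={"generator": "xcmasa.fixtures", "seed": spec.seed})
    else:
        lib = make_template_library(spec.n_templates, int(rng.integers(2**31)),
                                    site_size=spec.site_size)

    positives = []
    parents = [t for t in lib if not t.is_subtemplate]
    for i in range(spec.n_positives):
        decoy = make_decoy(spec.n_residues, int(rng.integers(2**31)),
                           structure_id=f"pos{i:03d}")
        t = parents[i % len(parents)]
        planted, truth = plant_site(decoy, t, spec.jitter_sigma, int(rng.integers(2**31)))
        positives.append(LabeledQuery(structure=planted, label=Label.POSITIVE,
                                      truth_site=truth))

    if spec.mutation == "alanine_scan":
        positives = alanine_scan_set(positives, seed=int(rng.integers(2**31)))
    if spec.delete_fa_of is not None:
        positives = [
            LabeledQuery(structure=delete_side_chain(q.structure,
                                                     q.truth_site[spec.delete_fa_of]),
                         label=q.label, truth_site=q.truth_site,
                         mutated_residue=q.truth_site[spec.delete_fa_of])
            for q in positives
        ]

    negatives = [LabeledQuery(structure=make_decoy(spec.n_residues,
                                                   int(rng.integers(2**31)),
                                                   structure_id=f"neg{i:03d}"),
                              label=Label.NEGATIVE)
                 for i in range(spec.n_negatives)]
    return positives + negatives, lib


def write_benchmark(queries, lib, out_dir) -> str:
    """Write PDB files, sites.tsv and manifest.tsv; returns the manifest path."""
    import pandas as pd

    from .templates import write_library

    os.makedirs(out_dir, exist_ok=True)
    pdb_dir = os.path.join(out_dir, "structures")
    os.makedirs(pdb_dir, exist_ok=True)
    rows, site_rows = [], []
    for q in queries:
        path = os.path.join(pdb_dir, f"{q.structure.structure_id}.pdb")
        with open(path, "w") as fh:
            fh.write(write_pdb(q.structure))
        truth = ";".join(f"{i.chain}:{i.seq_number}:{i.insertion_code}:{i.res_type}"
                         for i in q.truth_site)
        mut = ""
        if q.mutated_residue is not None:
            m = q.mutated_residue
            mut = f"{m.chain}:{m.seq_number}:{m.insertion_code}:{m.res_type}"
        rows.append({"path": os.path.relpath(path, out_dir), "label": q.label.value,
                     "truth_site": truth, "mutated_residue": mut})
        for i in q.truth_site:
            site_rows.append({"structure_id": q.structure.structure_id, "chain": i.chain,
                              "seq_number": i.seq_number, "icode": i.insertion_code,
                              "res_type": i.res_type})
    manifest = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    pd.DataFrame(site_rows).to_csv(os.path.join(out_dir, "sites.tsv"), sep="\t", index=False)
    write_library(lib, os.path.join(out_dir, "library.jsonl"))
    return manifest


def read_manifest(manifest_path):
    """Re-read a written benchmark into LabeledQuery objects."""
    import pandas as pd

    from .structure_io import read_pdb

    base = os.path.dirname(os.path.abspath(manifest_path))
    df = pd.read_csv(manifest_path, sep="\t", dtype=str, keep_default_na=False)
    queries = []
    for _, row in df.iterrows():
        model = read_pdb(os.path.join(base, row["path"]))
        truth = tuple(Identity(c, int(s), ic, rt)
                      for c, s, ic, rt in (x.split(":") for x in row["truth_site"].split(";") if x))
        mut = None
        if row.get("mutated_residue"):
            c, s, ic, rt = row["mutated_residue"].split(":")
            mut = Identity(c, int(s), ic, rt)
        label = Label(row["label"])
        queries.append(LabeledQuery(structure=model, label=label,
                                    truth_site=truth, mutated_residue=mut))
    return queries
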