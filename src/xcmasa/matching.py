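"""The search engine: residue-type filtering, local-structure emulation,
CMAD scoring, and library-wide search with postprocessing.

Given a template t_i of n residues and a query structure, the engine keeps
the query residues whose type matches some template residue (optionally up to
a substitution relation), emulates every assignment of distinct candidates to
template slots (*local structures*), and accepts an assignment when the
contact-matrix average deviation

    CMAD = mean over unordered pairs (j,k) of |d(t_i[j],t_i[k]) − d(lq[j],lq[k])|

is within the cutoff for both the Cα and the fa distance matrices.  Partial
assignments are pruned as soon as any single pair deviates by more than the
cutoff (sound, because the acceptance requires every pair within cutoff on
both matrices).  Accepted local structures are scored by superposition RMSD
and an extreme-value p-value; matches on n−1 subtemplates that are subsumed
by a match on their parent template are filtered out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .config import SearchConfig
from .errors import ValidationError
from .statistics import (load_abundance_table, load_evd_params, p_value,
                         superpose_rmsd)
from .structure_io import ResiduePoint, StructureModel, derive_residue_points
from .templates import Template, TemplateLibrary

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


class SubstitutionMatrix:
    """Symmetric boolean interchangeability relation over the 20 types.

    The diagonal is always 1 (every type is interchangeable with itself).
    """

    def __init__(self, pairs=()):
        self._allowed = {(a, a) for a in AMINO_ACIDS}
        for a, b in pairs:
            self._validate(a), self._validate(b)
            self._allowed.add((a, b))
            self._allowed.add((b, a))

    @staticmethod
    def _validate(t):
        if t not in AMINO_ACIDS:
            raise ValidationError(f"unknown amino-acid type {t!r}")

    def allows(self, a: str, b: str) -> bool:
        return (a, b) in self._allowed

    def interchangeable(self, t: str):
        return sorted(b for a, b in self._allowed if a == t)

    @classmethod
    def identity(cls) -> "SubstitutionMatrix":
        return cls()

    @classmethod
    def read_tsv(cls, path) -> "SubstitutionMatrix":
        """Read a 20×20 0/1 grid with amino-acid header row and column."""
        import pandas as pd

        from .errors import FormatError

        df = pd.read_csv(path, sep="\t", index_col=0)
        cols, rows = list(df.columns), list(df.index)
        if sorted(cols) != sorted(AMINO_ACIDS) or sorted(rows) != sorted(AMINO_ACIDS):
            raise FormatError(f"{path}: substitution matrix must be a 20×20 amino-acid grid")
        pairs = []
        for a in rows:
            for b in cols:
                v = int(df.loc[a, b])
                if v not in (0, 1):
                    raise FormatError(f"{path}: entries must be 0/1, got {v} at ({a},{b})")
                if v and int(df.loc[b, a]) != 1:
                    raise FormatError(f"{path}: relation not symmetric at ({a},{b})")
                if v:
                    pairs.append((a, b))
        return cls(pairs)

    def write_tsv(self, path) -> None:
        import pandas as pd

        grid = pd.DataFrame(
            [[1 if self.allows(a, b) else 0 for b in AMINO_ACIDS] for a in AMINO_ACIDS],
            index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
        grid.to_csv(path, sep="\t")


@dataclass(frozen=True)
class LocalStructure:
    """One candidate correspondence: query residues position-aligned to a template."""

    template_id: str
    correspondence: tuple  # of Identity, length n_ti, all distinct


@dataclass(frozen=True)
class MatchResult:
    template_id: str
    parent_template: str | None
    matched_residues: tuple  # of Identity
    cmad_ca: float
    cmad_fa: float
    rmsd: float
    p_value: float | None  # None until significance is attached
    is_subtemplate: bool

    def __post_init__(self):
        if min(self.cmad_ca, self.cmad_fa, self.rmsd) < 0:
            raise ValidationError("CMAD and RMSD must be non-negative")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value must lie in [0,1]")


def cmad(dists_t, dists_q) -> float:
    """Contact-matrix average deviation between corresponding pair distances."""
    a = np.asarray(dists_t, dtype=float)
    b = np.asarray(dists_q, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError(f"pair-distance sets must correspond: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def filter_candidates(points, t: Template, sm: SubstitutionMatrix | None = None):
    """Per-slot candidate lists: query residues type-compatible with each slot.

    Residues without a usable fa atom are never candidates — a site whose fa
    is missing in the file is invisible to the full template and must be
    recovered through a subtemplate.
    """
    usable = [p for p in points if p.has_fa]
    out = []
    for slot_type in t.res_types:
        if sm is None:
            out.append([p for p in usable if _one(p) == slot_type])
        else:
            out.append([p for p in usable if sm.allows(slot_type, _one(p))])
    return out


def _one(p: ResiduePoint) -> str:
    from .structure_io import protein_letters_3to1

    return protein_letters_3to1[p.identity.res_type]


def enumerate_local_structures(candidates, t: Template):
    """Yield every assignment of distinct query residues to template slots.

    Deterministic order: slot-major depth-first, candidates in structure order.
    """
    n = len(candidates)
    assignment = [None] * n

    def rec(j):
        if j == n:
            yield LocalStructure(t.template_id,
                                 tuple(p.identity for p in assignment))
            return
        for p in candidates[j]:
            if any(p.identity == q.identity for q in assignment[:j]):
                continue
            assignment[j] = p
            yield from rec(j + 1)
        assignment[j] = None

    yield from rec(0)


# ---------------------------------------------------------------------------
# Combination counting for the substitution-matrix vs subtemplate comparison.

@dataclass(frozen=True)
class Base:
    """Plain type filtering, no substitutions."""


@dataclass(frozen=True)
class Single:
    """One substitution x↔y: x-type query residues may fill y-type slots.

    ``counting="total"`` counts all assignments of the widened pools;
    ``counting="new"`` counts only those not already present in the base case.
    """

    x: str
    y: str
    counting: str = "total"


@dataclass(frozen=True)
class Simultaneous:
    """Two x-type residues simultaneously fill the y- and z-type slots.

    The pair of substitutable residues is unordered: occupying (y←x1, z←x2)
    and (y←x2, z←x1) count once.
    """

    x: str
    targets: tuple  # (y, z)


@dataclass(frozen=True)
class Subtemplates:
    """Assignments contributed by all size n−k subtemplates (base pools)."""

    k: int = 1


def count_combinations(query_types, template_types, scenario) -> int:
    """Count candidate local structures under one substitution scenario.

    *query_types* is the multiset of (filtered or unfiltered) query residue
    types, one letter each; *template_types* the template's slot types.  Pure
    counting over residue identities, no geometry.
    """
    q = list(query_types)
    slots = list(getattr(template_types, "res_types", template_types))

    def assignments(pools):
        count = 0
        for combo in itertools.product(*pools):
            if len(set(combo)) == len(combo):
                count += 1
        return count

    def base_pools(slot_types):
        return [[i for i, ty in enumerate(q) if ty == s] for s in slot_types]

    if isinstance(scenario, Base):
        return assignments(base_pools(slots))

    if isinstance(scenario, Single):
        pools = [[i for i, ty in enumerate(q) if ty == s or (s == scenario.y and ty == scenario.x)]
                 for s in slots]
        total = assignments(pools)
        if scenario.counting == "total":
            return total
        if scenario.counting == "new":
            return total - assignments(base_pools(slots))
        raise ValidationError(f"unknown counting convention {scenario.counting!r}")

    if isinstance(scenario, Simultaneous):
        y, z = scenario.targets
        xs = [i for i, ty in enumerate(q) if ty == scenario.x]
        pools = []
        for s in slots:
            if s in (y, z):
                pools.append(xs)
            else:
                pools.append([i for i, ty in enumerate(q) if ty == s])
        ordered = assignments(pools)
        # the two substituted slots draw from the same pool: halve for unordered
        return ordered // 2 if y != z else ordered

    if isinstance(scenario, Subtemplates):
        total = 0
        for kept in itertools.combinations(range(len(slots)), len(slots) - scenario.k):
            total += assignments(base_pools([slots[i] for i in kept]))
        return total

    raise ValidationError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# Geometric matching.

def match_template(points, t: Template, cmad_cutoff: float,
                   sm: SubstitutionMatrix | None = None):
    """All local structures of *points* matching *t* within the CMAD cutoff.

    Backtracking over slots with incremental per-pair pruning on both the Cα
    and fa distance matrices; each surviving assignment is scored (CMAD on
    both matrices, superposition RMSD over the 2n points).  Significance is
    not attached here.
    """
    if cmad_cutoff <= 0:
        raise ValidationError("cmad_cutoff must be > 0")
    candidates = filter_candidates(points, t, sm)
    if any(not c for c in candidates):
        return []
    n = t.n
    t_ca = np.array([r.ca for r in t.residues])
    t_fa = np.array([r.fa for r in t.residues])
    dt_ca = np.linalg.norm(t_ca[:, None] - t_ca[None, :], axis=-1)
    dt_fa = np.linalg.norm(t_fa[:, None] - t_fa[None, :], axis=-1)

    results = []
    assignment: list[ResiduePoint] = [None] * n

    def rec(j):
        if j == n:
            results.append(_score(assignment))
            return
        for p in candidates[j]:
            if any(p.identity == a.identity for a in assignment[:j]):
                continue
            ok = True
            for i in range(j):
                a = assignment[i]
                if abs(np.linalg.norm(p.ca - a.ca) - dt_ca[i, j]) > cmad_cutoff or \
                   abs(np.linalg.norm(p.fa - a.fa) - dt_fa[i, j]) > cmad_cutoff:
                    ok = False
                    break
            if ok:
                assignment[j] = p
                rec(j + 1)
        assignment[j] = None

    def _score(assign):
        q_ca = np.array([p.ca for p in assign])
        q_fa = np.array([p.fa for p in assign])
        pairs = list(itertools.combinations(range(n), 2))
        c_ca = cmad([dt_ca[i, j] for i, j in pairs],
                    [np.linalg.norm(q_ca[i] - q_ca[j]) for i, j in pairs])
        c_fa = cmad([dt_fa[i, j] for i, j in pairs],
                    [np.linalg.norm(q_fa[i] - q_fa[j]) for i, j in pairs])
        rmsd = superpose_rmsd(np.vstack([t_ca, t_fa]), np.vstack([q_ca, q_fa]))
        return MatchResult(
            template_id=t.template_id,
            parent_template=t.parent_template,
            matched_residues=tuple(p.identity for p in assign),
            cmad_ca=c_ca, cmad_fa=c_fa, rmsd=rmsd,
            p_value=None, is_subtemplate=t.is_subtemplate)

    rec(0)
    # per-pair pruning guarantees every pair ≤ cutoff, hence both means are too
    return [m for m in results if m.cmad_ca <= cmad_cutoff and m.cmad_fa <= cmad_cutoff]


def postprocess_matches(matches):
    """Drop subtemplate matches subsumed by a match on their parent template.

    A subtemplate match is removed iff its parent template also produced an
    accepted match whose residue set is a superset of the subtemplate match's
    residues; order is otherwise preserved.
    """
    by_template: dict[str, list[frozenset]] = {}
    for m in matches:
        by_template.setdefault(m.template_id, []).append(frozenset(m.matched_residues))
    out = []
    for m in matches:
        if m.is_subtemplate:
            sub = frozenset(m.matched_residues)
            parents = by_template.get(m.parent_template, [])
            if any(sub <= pset for pset in parents):
                continue
        out.append(m)
    return out


def search(q: StructureModel, lib: TemplateLibrary, cfg: SearchConfig | None = None,
           cmad_cutoff: float | None = None, sm: SubstitutionMatrix | None = None,
           abundance=None, evd=None):
    """Search a query structure against a whole template library.

    Every template (originals and subtemplates) is matched at the CMAD cutoff
    (the extended default applies automatically when the library contains
    subtemplates, unless *cmad_cutoff* overrides it), significance is
    attached, matches above the p-value threshold are discarded, subsumed
    subtemplate matches are postprocessed away, and the survivors are ranked
    by ascending p-value, then cmad_fa, then template_id.
    """
    cfg = cfg or SearchConfig()
    if len(lib) == 0:
        raise ValidationError("template library is empty")
    if not q.residues:
        raise ValidationError("query structure has no residues")
    cutoff = cmad_cutoff if cmad_cutoff is not None else cfg.cutoff_for_library(lib)
    if cutoff <= 0:
        raise ValidationError("cmad_cutoff must be > 0")
    table = abundance if abundance is not None else load_abundance_table(cfg.abundance_path)
    params = evd if evd is not None else load_evd_params(cfg.evd_path)
    if sm is None and cfg.sm_path:
        sm = SubstitutionMatrix.read_tsv(cfg.sm_path)

    points = derive_residue_points(q)
    accepted = []
    for t in lib:
        for m in match_template(points, t, cutoff, sm):
            score = p_value(m.rmsd, t.res_types, table, params, sm)
            if score.p_value <= cfg.p_threshold:
                accepted.append(replace(m, p_value=score.p_value))
    accepted = postprocess_matches(accepted)
    accepted.sort(key=lambda m: (m.p_value, m.cmad_fa, m.template_id))
    return accepted
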