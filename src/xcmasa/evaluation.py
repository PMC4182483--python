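"""Benchmark harness: alanine-scan test-set construction, TP/FN/FP/TN
classification, and confusion-matrix performance metrics.

A *positive* query carries an annotated catalytic site; a *negative* query is
a structure with no catalytic function.  A positive counts as a true positive
when some significant match recovers the truth site exactly — the full site
for unmutated queries, or exactly the non-mutated residues for
alanine-scanned queries (the subtemplate criterion, since the mutated residue
is unrecoverable by construction).  A negative with any significant match is
a false positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import SearchConfig
from .errors import ValidationError
from .matching import search
from .structure_io import Identity, StructureModel, mutate_to_alanine

log = logging.getLogger(__name__)


class Label(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Outcome(Enum):
    TP = "TP"
    FN = "FN"
    FP = "FP"
    TN = "TN"


class Mode(Enum):
    FULL = "full"            # truth site must be recovered exactly
    NON_MUTATED = "non-mutated"  # truth site minus the mutated residue


@dataclass
class LabeledQuery:
    structure: StructureModel
    label: Label
    truth_site: tuple = ()          # of Identity; non-empty iff POSITIVE
    mutated_residue: Identity | None = None

    def __post_init__(self):
        if (self.label is Label.POSITIVE) != bool(self.truth_site):
            raise ValidationError("truth_site must be non-empty exactly for positives")
        if self.mutated_residue is not None and self.mutated_residue not in self.truth_site:
            raise ValidationError("mutated_residue must belong to truth_site")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")


@dataclass(frozen=True)
class PerformanceReport:
    counts: ConfusionCounts
    sn: float
    acc: float
    pr: float
    mcc: float
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        c = self.counts
        return (f"TP={c.tp} FN={c.fn} FP={c.fp} TN={c.tn}  "
                f"Sn={self.sn:.3f} Acc={self.acc:.3f} Pr={self.pr:.3f} MCC={self.mcc:.3f}")


def alanine_scan_set(positives, seed: int):
    """Alanine-scan every positive query: mutate one random catalytic residue.

    For each query one uniformly chosen catalytic residue (GLY/ALA excluded)
    is substituted by alanine; sites with no mutable residue are skipped with
    a warning.  Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    out = []
    for q in positives:
        if q.label is not Label.POSITIVE:
            raise ValidationError("alanine_scan_set expects positive queries")
        mutable = [i for i in q.truth_site if i.res_type not in ("GLY", "ALA")]
        if not mutable:
            log.warning("%s: no mutable catalytic residue; skipped", q.structure.structure_id)
            continue
        target = mutable[int(rng.integers(len(mutable)))]
        mutated_model = mutate_to_alanine(q.structure, target.chain, target.seq_number,
                                          target.insertion_code)
        out.append(LabeledQuery(
            structure=mutated_model,
            label=Label.POSITIVE,
            truth_site=q.truth_site,
            mutated_residue=target,
        ))
    return out


def _same_residues(a, b) -> bool:
    # the mutated residue changes type in the structure, so compare positions
    return {i[:3] for i in a} == {i[:3] for i in b}


def classify(q: LabeledQuery, matches, mode: Mode = Mode.FULL) -> Outcome:
    """Classify one query given its (already p-filtered) ranked matches."""
    if q.label is Label.NEGATIVE:
        return Outcome.FP if matches else Outcome.TN
    if mode is Mode.NON_MUTATED:
        if q.mutated_residue is None:
            raise ValidationError("NON_MUTATED classification needs mutated_residue")
        target = tuple(i for i in q.truth_site if i != q.mutated_residue)
    else:
        target = q.truth_site
    for m in matches:
        if _same_residues(m.matched_residues, target):
            return Outcome.TP
    return Outcome.FN


def metrics(c: ConfusionCounts, config: dict | None = None) -> PerformanceReport:
    """Sensitivity, accuracy, precision and Matthews correlation coefficient.

    Zero denominators yield NaN with a warning, except the MCC where the
    0/0 case is reported as 0 by convention.
    """
    tp, fn, fp, tn = c.tp, c.fn, c.fp, c.tn

    def ratio(num, den, name):
        if den == 0:
            log.warning("metric %s undefined (zero denominator); reporting NaN", name)
            return float("nan")
        return num / den

    sn = ratio(tp, tp + fn, "sensitivity")
    acc = ratio(tp + tn, tp + fn + fp + tn, "accuracy")
    pr = ratio(tp, tp + fp, "precision")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        log.warning("MCC denominator zero; reporting 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return PerformanceReport(counts=c, sn=sn, acc=acc, pr=pr, mcc=mcc,
                             config=dict(config or {}))


def run_benchmark(queries, lib, cfg: SearchConfig | None = None,
                  mode: Mode | None = None, cmad_cutoff: float | None = None,
                  abundance=None, evd=None, per_query=None) -> PerformanceReport:
    """Search every query, classify, and aggregate into a performance report.

    *mode* defaults to NON_MUTATED when any query carries a mutated residue,
    FULL otherwise.  *per_query*, if given, is a list that receives
    (structure_id, outcome, matches) triples for inspection.
    """
    cfg = cfg or SearchConfig()
    if mode is None:
        mode = (Mode.NON_MUTATED
                if any(q.mutated_residue is not None for q in queries) else Mode.FULL)
    tally = {o: 0 for o in Outcome}
    for q in queries:
        matches = search(q.structure, lib, cfg, cmad_cutoff=cmad_cutoff,
                         abundance=abundance, evd=evd)
        q_mode = mode
        if q.label is Label.POSITIVE and mode is Mode.NON_MUTATED and q.mutated_residue is None:
            q_mode = Mode.FULL
        outcome = classify(q, matches, q_mode)
        tally[outcome] += 1
        if per_query is not None:
            per_query.append((q.structure.structure_id, outcome, matches))
    counts = ConfusionCounts(tp=tally[Outcome.TP], fn=tally[Outcome.FN],
                             fp=tally[Outcome.FP], tn=tally[Outcome.TN])
    echo = {"cmad_cutoff": cmad_cutoff if cmad_cutoff is not None else cfg.cutoff_for_library(lib),
            "p_threshold": cfg.p_threshold, "mode": mode.value,
            "library_size": len(lib)}
    return metrics(counts, config=echo)


def cmad_sweep(queries, lib, cutoffs, cfg: SearchConfig | None = None,
               mode: Mode | None = None, abundance=None, evd=None) -> dict:
    """Benchmark at several CMAD cutoffs; returns {cutoff: PerformanceReport}."""
    return {c: run_benchmark(queries, lib, cfg, mode=mode, cmad_cutoff=c,
                             abundance=abundance, evd=evd)
            for c in cutoffs}
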