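"""Match significance: superposition RMSD, abundance product θ, and the
extreme-value p-value.

A tentative geometric match is scored by the least-squares superposition RMSD
(R_M) between the template's 2n points and the matched query points.  Its
significance follows the extreme-value model used for local-structure database
searches: an expectation function EF(R_M) estimates how many matches at least
this good a scan of a typical structure would produce at random, and

    p = 1 − exp(−EF(R_M))

is the probability of at least one such random match.  EF is proportional to
θ, the product of the background abundances of the matched residue types
(rare residue combinations are harder to hit by chance), grows exponentially
with the RMSD allowance, and shrinks with the number of matched residues n:

    EF(R_M; θ, n) = θ · exp(a·R_M − b·n − c),      a > 0.

The constants are configuration data (see ``data/evd_params.yaml``), not code;
``docs/methods.md`` records how the defaults were calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from Bio.SVDSuperimposer import SVDSuperimposer

from .errors import ValidationError

#: p-values below the double-precision floor print as "<2.3e-16" and compare as 0.
P_FLOOR = 2.3e-16


@dataclass(frozen=True)
class AbundanceTable:
    """Background amino-acid frequencies (fractions summing to 1)."""

    freq: dict  # one-letter code -> fraction
    source_id: str = ""

    def __post_init__(self):
        if len(self.freq) != 20:
            raise ValidationError(f"abundance table needs all 20 types, got {len(self.freq)}")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"abundance frequencies sum to {total}, not 1")
        if not all(0.0 < f < 1.0 for f in self.freq.values()):
            raise ValidationError("abundance frequencies must lie in (0,1)")


@dataclass(frozen=True)
class EvdParams:
    """Constants of the expectation function EF(R_M) = θ·exp(a·R_M − b·n − c)."""

    a: float  # Å⁻¹, slope in RMSD; must be > 0 so EF is strictly increasing
    b: float  # per-residue penalty
    c: float  # overall scale offset

    def __post_init__(self):
        if not self.a > 0:
            raise ValidationError("EVD parameter a must be > 0 (EF must increase with RMSD)")

    def ef(self, rmsd: float, theta: float, n: int) -> float:
        return theta * math.exp(self.a * rmsd - self.b * n - self.c)


@dataclass(frozen=True)
class SignificanceScore:
    rmsd: float
    ef: float
    p_value: float

    def display(self) -> str:
        return f"<{P_FLOOR:.1e}" if self.p_value < P_FLOOR else f"{self.p_value:.3e}"


def load_abundance_table(path=None) -> AbundanceTable:
    """Load an abundance TSV (columns: res_type one-letter, frequency).

    Frequencies are normalised to sum exactly to 1.  The default table ships
    with the package (Swiss-Prot background composition).
    """
    import pandas as pd

    if path is None:
        with resources.files("xcmasa.data").joinpath("abundance_swissprot.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        source = "swissprot-background"
    else:
        df = pd.read_csv(path, sep="\t")
        source = str(path)
    freq = dict(zip(df["res_type"], df["frequency"].astype(float)))
    total = sum(freq.values())
    freq = {k: v / total for k, v in freq.items()}
    return AbundanceTable(freq=freq, source_id=source)


def load_evd_params(path=None) -> EvdParams:
    if path is None:
        with resources.files("xcmasa.data").joinpath("evd_params.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    try:
        return EvdParams(a=float(raw["a"]), b=float(raw["b"]), c=float(raw["c"]))
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"EVD parameter file must define a, b, c: {exc}") from exc


def superpose_rmsd(points_a, points_b) -> float:
    """Minimal RMSD between two ordered point sets over rigid motions.

    Rotation + translation only (no reflection); symmetric in its arguments.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 2:
        raise ValidationError(f"point sets must be equal-shaped (m,3), m≥2: {a.shape} vs {b.shape}")
    sup = SVDSuperimposer()
    sup.set(a, b)
    sup.run()
    return float(sup.get_rms())


def abundance_product(types, table: AbundanceTable) -> float:
    """θ: product of background frequencies of the residue types (one-letter)."""
    theta = 1.0
    for t in types:
        if t not in table.freq:
            raise ValidationError(f"residue type {t!r} not in abundance table")
        theta *= table.freq[t]
    return theta


def effective_theta(types, table: AbundanceTable, sm=None) -> float:
    """θ under an optional substitution relation.

    With a substitution matrix each template slot accepts every interchangeable
    type, so the slot's effective abundance is the *sum* of the abundances of
    the allowed types — enlarging the relation therefore always raises θ and
    with it the p-value.
    """
    if sm is None:
        return abundance_product(types, table)
    theta = 1.0
    for t in types:
        if t not in table.freq:
            raise ValidationError(f"residue type {t!r} not in abundance table")
        allowed = sm.interchangeable(t)
        theta *= min(sum(table.freq[u] for u in allowed if u in table.freq), 1.0)
    return theta


def p_value(rmsd: float, types, table: AbundanceTable, params: EvdParams,
            sm=None) -> SignificanceScore:
    """Significance of a match at superposition RMSD *rmsd* over *types*."""
    if rmsd < 0:
        raise ValidationError("rmsd must be non-negative")
    theta = effective_theta(types, table, sm)
    ef = params.ef(rmsd, theta, len(list(types)))
    p = float(-np.expm1(-ef))  # 1 − exp(−ef), accurate for tiny ef
    return SignificanceScore(rmsd=rmsd, ef=ef, p_value=min(max(p, 0.0), 1.0))
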