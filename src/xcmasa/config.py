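"""Shared search configuration."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass
class SearchConfig:
    """Thresholds and auxiliary inputs of a library search.

    ``cmad_cutoff`` (1.2 Å) is the default acceptance threshold on both the
    Cα and fa contact-matrix average deviations; for libraries extended with
    n−1 subtemplates a tighter 0.4 Å (``cmad_cutoff_extended``) is the
    recommended trade-off, because smaller templates raise the chance of
    random matches.  ``p_threshold`` (1e-4) gates statistical significance.
    """

    cmad_cutoff: float = 1.2
    cmad_cutoff_extended: float = 0.4
    p_threshold: float = 1.0e-4
    abundance_path: str | None = None
    evd_path: str | None = None
    sm_path: str | None = None
    k: int = 1
    min_size: int = 2

    def __post_init__(self):
        if self.cmad_cutoff <= 0 or self.cmad_cutoff_extended <= 0:
            raise ValidationError("CMAD cutoffs must be > 0")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValidationError("p-value threshold must lie in (0,1)")
        if self.k < 1 or self.min_size < 2:
            raise ValidationError("k must be ≥ 1 and min_size ≥ 2")

    def cutoff_for_library(self, lib) -> float:
        """1.2 Å default; the extended default when subtemplates are present."""
        if any(t.is_subtemplate for t in lib):
            return self.cmad_cutoff_extended
        return self.cmad_cutoff
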