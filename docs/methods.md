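# Methods

## The prediction problem

Catalytic residues — the handful of amino acids that carry out an enzyme's
chemistry — are conserved in geometry even when global sequence and fold
similarity to annotated enzymes is weak. `xcmasa` predicts them by local
structural comparison: a library of *templates*, each the geometry of one
annotated active site, is matched against candidate residue combinations in
a query structure.

## Residue representation

Every residue is reduced to two labelled points: its α-carbon (Cα) and the
side-chain heavy atom furthest from the Cα (*fa*).  The fa atom carries the
functional end of the side chain (Oγ of serine, Nζ of lysine, …) without
requiring full-atom modelling.  Conventions where the source method is
silent, chosen here and exposed in `structure_io`:

- **Glycine** has no side-chain heavy atom; we set fa := Cα so glycine-
  containing sites keep well-defined distance matrices.
- **Equidistant candidates** (e.g. arginine Nη1/Nη2 at identical distance)
  resolve to the lexicographically smallest atom name, for determinism.
- **Truncated side chains** (all side-chain atoms absent from the file)
  yield fa = ABSENT; such residues are invisible to the matcher (below).
- Alternate locations keep the highest-occupancy conformer (first in file on
  ties); hydrogens, waters, ligands and non-standard residues are dropped;
  only the first NMR model is read.  Coordinates are carried at full float
  precision internally and written at the PDB's three decimals.

## Templates, master templates, and the n−1 extension

A template is the ordered (Cα, fa) point set of the n catalytic residues of
one annotated enzyme.  Families of templates with identical residue-count
and type signature are summarised by a *master template*: the member t_i
minimising the mean superposition RMSD (1/n_r)·Σ_j RMSD(i, j) over the
family.  The mean includes the zero i = j term (the normalisation is
ambiguous in the method's published description; including it shifts every
candidate equally, so the argmin is unaffected).  Ties resolve to the
lexicographically smallest template id, with "tie" meaning within 1e-9 Å of
the minimal mean.

A full template cannot match a site in which one residue was substituted
(the type filter removes it) or lost its fa atom (the residue is excluded
from candidacy).  The extension is to add, for every template of size
n ≥ min_size + 1, all n subtemplates obtained by omitting one residue.  A
single point mutation then leaves exactly one subtemplate that still matches
the intact remainder.  For N_T templates of at most n_max residues the
library grows by at most N_T × n_max entries; omitting k > 1 residues is
supported but grows as binomial(n, k).  `min_size` defaults to 2 so
three-residue sites — the dominant case among small active sites — remain
recoverable after one mutation.

## Matching and the CMAD score

For a template t_i, query residues are filtered by type (optionally up to a
0/1 substitution relation), and every assignment of distinct candidates to
template slots is a candidate *local structure*.  An assignment matches when
the contact-matrix average deviation

CMAD = (1 / C(n,2)) · Σ_{j<k} | d(t_i[j], t_i[k]) − d(lq[j], lq[k]) |

is within the cutoff for **both** the Cα–Cα and fa–fa distance matrices.
Because acceptance requires every pair within the cutoff on both matrices, a
partial assignment can be abandoned as soon as one pair deviates beyond the
cutoff on either matrix; this pruning is exact (tested against prune-free
enumeration) and is what keeps library-wide search fast.

Default cutoffs: 1.2 Å for plain libraries; 0.4 Å when the library contains
subtemplates.  Smaller subtemplates match random geometry more easily, and
0.4 Å is the published trade-off between false positives on non-mutated
queries and false negatives on mutated ones.  On exact sites the extended
library's sensitivity is flat in the cutoff (matches score CMAD ≈ 0), which
the acceptance suite checks at 0.1 / 0.4 / 1.2 Å.

## Match significance

An accepted local structure is scored by the least-squares rigid
superposition RMSD R_M over its 2n points (Kabsch, via
`Bio.SVDSuperimposer`; no reflection).  Significance follows an
extreme-value model: the expectation function

EF(R_M) = θ · exp(a·R_M − b·n − c)

estimates the number of random matches at least this good in a scan of a
typical structure, and p = 1 − exp(−EF) is the probability of at least one.
θ is the product of the background abundances of the matched residue types
(Swiss-Prot composition, shipped as data and overridable); under a
substitution relation each slot's abundance is the sum over its
interchangeable types, which is why permissive substitution matrices inflate
p-values.  A match is reported when p ≤ 1e-4.  p-values below 2.3e-16 are
displayed as "<2.3e-16".

The three constants are configuration data (`data/evd_params.yaml`), not
code.  The published constants derive from a fit against a specific
non-redundant fold database we do not reconstruct, so the shipped defaults
were calibrated analytically against the two constraints the method's
published behaviour fixes: (i) a two-residue match (the smallest
subtemplate, θ ≈ 2.5e-3 for typical catalytic types) should cross p = 1e-4
near R_M ≈ 0.25 Å, so that random two-residue coincidences in non-catalytic
structures are rarely significant — consistent with the published
false-positive rate of a few percent of negatives; (ii) a three-residue
match (θ ≈ 1.25e-4) should cross near R_M ≈ 0.8 Å, so genuine sites match
comfortably.  Solving the two crossing conditions gives a = 12.0 Å⁻¹,
b = 3.6, c = −1.0.  Only a > 0 (EF strictly increasing in RMSD) is a
validity requirement; the loader enforces it.

## Benchmark harness

Queries are labelled positive (annotated site present) or negative.  After a
search, a positive is a true positive when some significant match equals the
truth site exactly — the full site for unmutated queries (mode FULL), or
exactly the site minus the mutated residue for alanine-scanned queries
(mode NON_MUTATED; the mutated residue is unrecoverable by construction, and
requiring the exact remainder keeps the criterion strict).  A negative with
any significant match is a false positive.  Metrics are the usual
sensitivity, accuracy, precision and Matthews correlation coefficient;
zero-denominator metrics are reported as NaN with a warning, except MCC
where 0/0 → 0 by the common convention.  Per-query outcomes can be
persisted for false-positive inspection, and a CMAD sweep reproduces the
cutoff-sensitivity curves.

Alanine scanning substitutes one uniformly chosen catalytic residue
(glycine and alanine excluded) per positive by alanine — the side chain is
truncated at Cβ and the residue retyped — deterministically under a seed.

## The synthetic-data generator

No external structures are downloaded; everything is generated:

- **Decoys** are self-avoiding pseudo-chains with consecutive Cα spacing
  3.8 ± 0.1 Å, ≥ 4 Å between non-adjacent residues, residue types drawn from
  the background abundances (glycine excluded so every residue has a usable
  fa), a Cβ at 1.53 Å and a type-appropriate distal atom 2.4–4 Å from Cα.
  They are geometric stand-ins, not physical proteins: no backbone carbonyl
  chemistry, no rotamers, no sequence plausibility.  This suffices because
  the matcher consumes only residue types and the two-point reduction —
  passing tests demonstrate the engine's behaviour under the method's
  assumptions, not performance on real crystal structures.
- **Templates** are synthetic three-residue sites (types drawn from the
  catalytically common D/E/H/K/S/T/C/R/N/Y; Cα pairwise 4–12 Å; fa 2.4–4 Å
  out), mirroring the three-residue filter applied to the published mutated
  test set.
- **Positives** are decoys with a template's geometry planted under a random
  rigid motion on non-adjacent residues, plus optional iid Gaussian jitter.
  The benchmark default is exact planting (jitter 0): it models the common
  benchmark situation where the annotated site's own coordinates are in the
  library's family.  Jitter sensitivity is exercised separately
  (expected CMAD grows monotonically with σ).
- **Benchmark grid**: 20 positives / 100 negatives of 150 residues against a
  20-template library — sizes at which the full 2×2
  (mutation × master/extended) grid runs in well under a minute on one CPU,
  while large enough that the sensitivity contrasts are not sampling noise.
  The false-positive regression guard uses 200 decoys.

All randomness flows through numpy's PCG64 (`default_rng`) from explicit
seeds; identical spec + seed reproduces identical output bytes.

## Numerical choices and degenerate inputs

- Superposition uses SVD with determinant correction (no reflections);
  point sets of fewer than 2 points are rejected.
- Match ranking is deterministic: ascending p-value, then cmad_fa, then
  template_id.
- Residues lacking a Cα are dropped with a warning; empty structures,
  empty libraries, and ATOM-free PDB text are errors.
- Library files are JSON-lines with a versioned header; any version or
  schema mismatch is a format error rather than a silent reinterpretation.

## Known limitations

- Decoys and planted sites are idealised; absolute benchmark numbers on this
  synthetic data (e.g. sensitivity 1.0 at zero jitter) are upper bounds, not
  estimates of performance on crystallographic data.
- The EVD constants are calibrated, not fitted to a fold database; absolute
  p-values are comparable within a run but not across methods.
- One chain convention: insertion codes are honoured but assemblies,
  mmCIF, nucleic acids and modified residues are out of scope.
- Counting for simultaneous substitutions supports the
  one-slot-per-substituted-type case used in the worked comparison.
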