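# Methods

This note records the model, the numerical conventions, the synthetic
data used for testing, and the design choices made where the published
protocol leaves room for interpretation.

## The conformational model

The unit of classification is the dinucleotide *step*: the fragment
from C5′ of nucleotide i to O3′ of nucleotide i+1, containing both
deoxyriboses, both bases and the linking phosphate. Conformation is
represented by nine torsions in a fixed order:

| torsion | atoms | of |
|---|---|---|
| δ  | C5′–C4′–C3′–O3′ | nt i |
| ε  | C4′–C3′–O3′–P   | i → i+1 |
| ζ  | C3′–O3′–P–O5′   | i → i+1 |
| α₁ | O3′–P–O5′–C5′   | i → i+1 |
| β₁ | P–O5′–C5′–C4′   | nt i+1 |
| γ₁ | O5′–C5′–C4′–C3′ | nt i+1 |
| δ₁ | C5′–C4′–C3′–O3′ | nt i+1 |
| χ  | O4′–C1′–N9–C4 (purine) / O4′–C1′–N1–C2 (pyrimidine) | nt i |
| χ₁ | ditto | nt i+1 |

plus the sugar pucker of each deoxyribose in the pseudorotation
description: P = atan2((ν₄+ν₁)−(ν₃+ν₀), 2ν₂(sin 36° + sin 72°)) with
the quadrant fixed by the sign of ν₂, and amplitude
τ = √(ν₂² + ((ν₄+ν₁−ν₃−ν₀)/2(sin 36°+sin 72°))²), which reduces to
ν₂/cos P and is exact for torsions on the cosine parameterization
νⱼ = τ·cos(P + 144°(j−2)).

All torsions follow the IUPAC sign convention and are reported on
[0, 360), the scale on which nucleic-acid backbone torsions are
conventionally quoted.

### Circular statistics

Class statistics use directional statistics throughout: the mean of a
torsion sample is the direction of the resultant unit-vector sum, and
the estimated standard deviation (esd) is the angular deviation
√(−2 ln R̄) in degrees. This is the only averaging convention
consistent with the circular distance metric used for classification;
for tightly clustered samples it agrees with the linear mean/sd to
well under 0.1°. Signed circular differences live in (−180°, 180°],
with the antipodal case mapped to +180° so that signed sums are
reproducible. A sample with (near-)zero resultant has no defined mean
and raises an error naming the class.

## Assignment protocol

Parameters, with defaults exactly as published and all of them
overridable via the CLI config file:

| parameter | default | role |
|---|---|---|
| k-max | 11 | neighbours ranked by circular Euclidean distance |
| k-min | 7 | minimum usable golden-set size |
| nn-cutoff | 0.0011 | minimum summed 1/d² weight of same-class neighbours (= 1/30²) |
| test1-limit | 28° | per-torsion proximity to the nearest neighbour and the same-class neighbour average |
| test2-esd-mult | 5 | per-torsion limit in class esd multiples |
| test3-limit | 60° | bound on the signed-difference sums (backbone 7; glycosidic 2) |
| test4-limit | 72° | bound on |P − class P mean| per sugar |

Conventions chosen where the protocol text is ambiguous:

- *Neighbourhood semantics.* The 11 nearest members are ranked; the
  tentative class is that of the single nearest neighbour; the weight
  sum, the same-class neighbour average of test 1, and nothing else,
  are computed over the same-class members among those 11. Reference
  sets smaller than 7 members are rejected outright.
- *Threshold edges.* All comparisons are inclusive: a displacement of
  exactly 28° (60°, 72°) passes; 28°+ε fails.
- *No short-circuiting.* All four tests are always evaluated so the
  diagnostics list every violated criterion; reason codes are
  WEIGHT_BELOW_CUTOFF, TEST1_NN_TORSION, TEST1_CLASSMEAN_TORSION,
  TEST2_ESD, TEST3_BACKBONE_SUM, TEST3_CHI_SUM, TEST4_PUCKER.
- *Exact duplicates.* 1/d² weights are capped at 1/(0.001°)² so a
  candidate identical to a golden member keeps a finite weight sum;
  any cap far above the cutoff leaves decisions unchanged.
- *Ties.* Equidistant neighbours are ordered by member id, making the
  ranking deterministic.

## Confal

confal = 100·exp(−Σ Δᵢ²/c²) over the nine torsions, with one c² per
class: c² = Σ lim_i²/ln 100 and lim_i = min(28°, 5·esdᵢ). The two
calibration identities — score 100 at zero displacement, score exactly
1 with every torsion at its limit — hold by construction and are
asserted per class in the test suite. The calibration reads "1 at the
limiting values" as *all nine* torsions simultaneously at their
limits; the alternative single-torsion reading would need a per-torsion
coefficient, which contradicts the one-coefficient-per-class
definition. Degenerate classes (all limits zero, possible only for
synthetic single-point classes) fall back to the c² of 1° limits so
the score stays defined. Unassigned steps score 0, and those zeros are
included in the structure-level arithmetic mean: the phrase "all
steps" is taken literally, and it makes the structure score penalize
unclassifiable geometry rather than hiding it.

Percentile ranks use the weak convention: the percentage of reference
structure scores ≤ the query. The packaged reference distribution is
synthetic (a fixed beta law with most mass between 60 and 80); the CLI
notes this whenever it is used. Empirical confal distributions of real
structure collections are not shipped.

## Structure input

Parsing is delegated to gemmi (PDB and mmCIF, dialect autodetected).
Only standard deoxyribonucleotides (DA, DC, DG, DT) are kept; modified
residues can be mapped to a parent base via an explicit name map,
otherwise they are excluded. Alternative conformations collapse to the
highest-occupancy atom, ties to the lexicographically smallest altloc.
Multi-model files use model 1 unless another index is requested.

Consecutive residues of a chain form a step only if the O3′–P distance
is ≤ 2.0 Å (≈25% above the ideal bond length, tolerant of poorly
refined models) and every atom needed for the nine torsions is
present; failing pairs are skipped with a logged reason rather than
treated as errors, so a chain of n linked nucleotides yields exactly
n−1 steps and skips are fully accounted. δ outside the physically
sensible 75–165° window flags the step but does not exclude it.

## Synthetic data

Because a curated experimental golden set is not distributable with
the package, all references and fixtures are generated:

- **Statistical fixtures** sample members from wrapped normals about
  specified class means (esds 4–5°, spacing 33° across all nine
  torsions for the default 10-class spec, enforced pairwise separation
  of at least 5× the largest esd in at least one torsion). Wrapped
  normals rather than von Mises: at esds ≪ 60° the two are
  indistinguishable and wrapped-normal sampling is trivially
  reproducible. Candidate generators scale the esds by a noise factor;
  P values are sampled with σ = 5°·noise.
- **The shipped 44-class reference** is constructed, not transcribed:
  each class takes its CANA family's canonical-geometry template
  (A-form, BI, BII, A/B intermediates, syn-χ, Z-form) plus a
  deterministic per-class offset on two non-sugar torsions, and
  members are reconstituted by seeded sampling (provenance is marked
  "reconstituted" in the metadata and the file is named
  `*_synthetic.tsv`). The class list contains 44 identifiers: every
  explicitly enumerated class of the CANA grouping plus the eight B-A
  classes BA01/05/08/09/10/13/16/17 consistent with public usage of
  the NtC vocabulary.
- **The coordinate builder** places atoms by internal-coordinate
  (NeRF) extension with fixed ideal bond lengths/angles and the
  requested dihedrals. The nine step torsions and χ geometry are
  honoured exactly (round-trip through build → write → parse →
  recompute is well under 0.01°; the high-precision mmCIF writer
  exists because fixed-column PDB coordinates cap the round-trip at
  ≈0.05°). Sugar rings are built with ν₂ and ν₃ exact and the O4′–C1′
  closure bond implied, so the P measured back from coordinates is
  within a few degrees of the request — ample for the ±72° pucker
  test. Requests no deoxyribose can realize (δ outside 75–165°, or δ
  inconsistent with the ring pucker by more than 45° from the
  geometric relation δ ≈ ν₃ + 121°) are rejected at build time.

What passing tests on these fixtures do **not** show: robustness to
experimental-data pathologies (disorder, refinement artefacts,
non-ideal covalent geometry, modified bases), or agreement with the
historical curated golden set's class boundaries. They do show that
the protocol's machinery — metric, ranking, cutoffs, calibration,
bookkeeping — behaves exactly as specified, since every decision is
cross-checked against independently coded naive oracles.

## Clustering

Draft-class discovery uses complete-linkage agglomeration on the
circular Euclidean distance matrix, implemented directly (O(n³),
adequate for curation-scale inputs) so that the documented tie-break —
equidistant pairs merge in order of their sorted member-id tuples —
makes labels invariant under input permutation. Dendrogram heights are
verified against scipy's complete linkage. The flat cut (default 60°)
and the minimum draft size (default 10) are parameters, since no
published values exist; proposals are always marked draft and never
merged into a shipped reference automatically.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen to exercise
every code path with comfortable statistical margins: golden sets of
10 classes × 30 members (plus 44 × 2–20 for the shipped reference),
500-candidate recovery experiments, 1000-candidate oracle
comparisons, 50-point clustering instances and 200-vector geometric
round-trips. The whole suite completes in well under a minute.

## Known limitations

- RNA, DNA/RNA hybrids and symmetry-mate expansion are out of scope;
  no structure repair or hydrogen handling is attempted.
- The shipped reference is synthetic; annotations of real structures
  against it are illustrative, not authoritative.
- The builder's rings are near-ideal, not energy-minimized; absolute
  geometry (base pairing, groove widths) is not modelled.
- Steps spanning altloc-mixed backbones are resolved to one conformer
  before extraction rather than enumerated.
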