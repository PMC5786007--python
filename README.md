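# ntcana

Dinucleotide-conformer annotation for DNA structures: assignment of
**NtC** (Nucleotide Conformer) classes by weighted k-nearest-neighbour
classification in nine-dimensional torsion space, reduction to the
**CANA** structural alphabet, and structure validation with the
Gaussian **confal** score.

## Who this is for

Structural biologists and bioinformaticians who want an offline,
scriptable way to characterize the backbone conformation of DNA in
crystal, NMR or modelled structures — naked DNA or protein–DNA
complexes — beyond the coarse A/BI/BII/Z labels: per-step conformer
classes, per-chain structural-alphabet strings and a quantitative
agreement score usable for validation.

## The method

A *step* is the dinucleotide fragment from C5′ of one nucleotide to
O3′ of the next: two deoxyriboses, two bases and the linking
phosphate. Its conformation is described by nine torsions in fixed
order — the backbone torsions δ, ε, ζ, α₁, β₁, γ₁, δ₁ and the two
glycosidic torsions χ, χ₁ — plus the pseudorotation phase P of each
sugar (Altona–Sundaralingam convention).

Classification is by weighted k-NN against a *golden set* of
classified reference steps:

1. Rank golden-set members by the circular Euclidean distance
   d = √Σᵢ Δᵢ², where Δᵢ is the componentwise shortest angular
   difference; keep the 11 nearest, each weighted 1/d².
2. Tentatively assign the class of the single nearest neighbour. If
   the summed weight of the ranked neighbours of that class falls
   below 0.0011 (= 1/30²), the step is unassigned (**NAN**).
3. Otherwise apply four rejection tests: (1) every torsion within 28°
   of both the nearest neighbour and the same-class neighbour average;
   (2) every torsion within 5 estimated standard deviations of the
   class mean; (3) the signed-difference sums within ±60° for the
   seven backbone torsions and for the two glycosidic torsions;
   (4) both sugar P values within ±72° of the class averages.

Assigned steps get a CANA letter (11 letters — AAA, A-B, B-A, BBB,
2B1, 3B1, B12, BB2, miB, SQX, ZZZ — plus NAN) and a confal score

    confal = 100 · exp(−Σᵢ Δᵢ² / c²),   c² = Σᵢ lim_i² / ln 100,
    lim_i = min(28°, 5·esdᵢ),

which is 100 for a step exactly at the class torsion averages, 1 for a
step displaced by its limiting value on every torsion, and 0 for NAN
steps. The structure-level confal is the arithmetic mean over all
steps (zeros included) and can be ranked against a reference
distribution of structure scores.

**Shipped reference.** The packaged default reference is *synthetic*:
44 classes of the NtC vocabulary with torsion statistics constructed
from canonical A/B/Z backbone geometry templates, reconstituted into
members by seeded sampling. It exercises the full machinery and gives
sensible annotations for idealized geometries, but it is not a curated
experimental golden set — supply your own member table via `--ref` for
production use.

## Worked example

Annotate a synthetic B-DNA-like duplex (two 12-nt chains built from a
canonical BI step geometry):

```sh
python - <<'PY'
from ntcana.synthetic import make_duplex_pdb
make_duplex_pdb("duplex.pdb")
PY
ntcana annotate --in duplex.pdb --out demo
```

which prints:

```
steps: 22
assigned: 22
unassigned (NAN): 0
skipped pairs: 0
structure confal: 99.8
percentile: 100 (reference: synthetic (packaged))
```

All 22 steps (11 per chain, n−1 per n-nucleotide chain) are assigned
to the canonical BI class BB00, so each chain's CANA string in
`demo.cana.txt` reads `BBB BBB … BBB`. The structure confal of 99.8
says the extracted torsions sit essentially at the BB00 class averages
(the 0.2 gap comes from the sampling noise of the reconstituted
reference members). `demo.steps.tsv` lists, per step: the nine
torsions, both puckers (P, τ), the assigned NtC, CANA letter, confal,
nearest-neighbour distance and any rejection reasons.

Draft-class discovery from a torsion table (written with
`--dump-torsions`) uses complete-linkage clustering on the same
circular metric:

```sh
ntcana annotate --in duplex.pdb --out demo --dump-torsions
ntcana cluster --torsions demo.torsions.tsv --cut 60 --min-size 10 --out drafts.tsv
```

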