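# Methods

This note documents the models, rules and numerical conventions behind
`nrcat`, and what the synthetic benchmark does and does not demonstrate.

## Sequence model and alignment

Sequences use the 20 standard amino acids plus `X`; coordinates are
0-based, half-open throughout. Scoring is BLOSUM62 (loaded from
Biopython's packaged NCBI-format tables) with affine gaps: a gap of length
k costs `gap_open + k·gap_extend`, default 11/1 — the conventional
protein-search defaults, used because the surveyed protocol relied on
default BLAST/ClustalX parameters without stating them.

Three alignment modes are implemented as Gotoh dynamic programs
(numba-compiled, exact optima):

* **global** (Needleman–Wunsch) — both sequences end to end;
* **local** (Smith–Waterman) — best positively scoring island;
* **semi-global** — the reference fully aligned, the candidate's flanks
  free; used to locate a domain-sized reference inside a full-length
  protein. Plain global alignment is unsuitable there because end-gap
  penalties on the candidate's N-terminal and hinge regions would distort
  the normalized score (a reference aligned to itself inside its own
  full-length sequence must score exactly 1.0).

Traceback ties break deterministically: diagonal over gap-in-first over
gap-in-second. Tests verify optimality against exhaustive enumeration of
all gapped alignments (short pairs) and against an independent C
implementation (longer pairs).

`percent_identity` divides identical columns by the *reference-side*
aligned residues — the denominator convention for all similarity values in
the package, so similarities are percentages of the reference (human)
domain.

The progressive multiple aligner builds an NJ guide tree from pairwise
p-distances and merges profiles by sum-of-pairs profile–profile alignment
with the same affine penalties; no iterative refinement, which is adequate
for the ≤ 35-taxon, high-identity alignments this workflow produces.

## Reference templates and the synthetic benchmark

The packaged manifest lists the 48 human NR symbols (NR0B1…NR6A1, seven
subfamilies, trivial names). Templates are realised from a structural
grammar rather than real sequences:

* **DBD** (absent in NR0B1/NR0B2): 2-residue lead, zinc-finger motif
  `C-x2-C-x13-C-x2-C`, 15-residue inter-finger linker,
  `C-x5-C-x9-C-x2-C`, then a C-terminal extension of 17–22 residues so the
  whole domain spans 75–80 aa.
* **LBD**: 12 helices separated by 1-residue loops; helices 1, 2, 11, 12
  are short flanks and helices 3–10 are sized so the *core* interval —
  12th residue of helix 3 through the end of helix 10, the segment the
  annotator extracts — spans 172–182 aa while the full bundle stays within
  170–210 aa. Both windows therefore hold simultaneously.
* Flanking N-terminal, hinge and tail segments are random; templates are
  rejection-sampled to pairwise identity < 70%.

Evolution along the species tree is a Poisson replacement process: on a
branch of length `t`, each site mutates with probability
`1 − exp(−t·m_region)`, the replacement uniform over the 19 alternatives.
Region multipliers (DBD 0.3, LBD 0.6, linker 1.0) encode the observed
conservation ordering DBD > LBD > linker. Zinc-finger cysteines are
immutable, and indels are not simulated, so true domain coordinates remain
valid in every descendant — this is what makes boundary recovery exactly
checkable. Duplication and loss act per gene per branch (default
probability 0.004 each), plus two scripted events that reproduce
well-known lineage patterns: loss of NR1I2 (PXR) on the bird stem and a
teleost-ancestor duplication of NR1F3 (RORγ). Decoys are i.i.d. random
proteins (uniform composition, length ≈ N(350, 80²), ≥ 60) rejected if
they happen to contain the double-finger motif.

The default 12-leaf tree names the classic toxicological model species
(human, mouse, rat, dolphin, chicken, duck, turtle, frog, zebrafish,
medaka, tilapia, stickleback); branch lengths are expected substitutions
per site at the linker rate, with root-to-tip depths ≤ 0.2 so the
benchmark sits inside the divergence regime where full recovery is the
correct expectation. The dolphin branch is deliberately shorter than the
rodent path so the relative-proximity summary has a known direction.

**What the benchmark does not emulate:** indels, rate heterogeneity across
sites, empirical substitution preferences, alternative splicing, assembly
gaps or annotation errors. Perfect precision/recall on this benchmark
demonstrates internal correctness of the pipeline's logic, not expected
performance on real proteomes.

## Homology search and calibration

Queries are each template's concatenated DBD+LBD (LBD alone for NR0B), per
the domain-based search strategy. Search: exact k-mer seeding (k = 4),
seeds grouped by (target, diagonal), ungapped X-drop extension (X = 20),
and an exact Smith–Waterman alignment for any target whose best diagonal
reaches the trigger score (25). At desk scale (targets ≤ ~10³ residues)
the gapped stage is run unbanded, so reported scores are exact local
optima by construction. Only the best hit per (query, target) is kept.

E-values use `E = K·m·n·e^(−λS)` with λ solved from
`Σ pᵢpⱼ e^(λ·sᵢⱼ) = 1` (Brent root-finding, residual < 1e−9, uniform
background by default) and K a documented constant (0.13): within one
database only the ordering and threshold semantics of E matter, not its
absolute calibration.

The cutoff is not fixed a priori. `calibrate_cutoff` returns the loosest
per-gene requirement — the max over the calibration proteome's known NR
genes of their best-hit E — guaranteeing full recall there. Because that
guarantee is exact only for the calibration species, the pipeline applies
the cutoff with a safety margin (default 10⁶): the calibration species
should be chosen maximally diverged (the pipeline default calibrates on
zebrafish), and the margin absorbs residual score fluctuation between
equally deep lineages. True-gene E-values sit ~10⁻⁶⁰ and below while
decoys cannot pass ~10⁻⁵, so the margin costs nothing in precision.

## Domain annotation and verification

DBD: the motif detector accepts inter-finger linkers of 13–19 residues
(finger-internal spacing exact); the first (most N-terminal) match is the
DBD, so stray upstream cysteines cannot shift the boundary. The annotated
segment starts 2 residues before the first motif cysteine (clamped at 0
with a warning), ends 12 residues after the last cysteine, and is then
extended/truncated into the 75–80 window — the window is canonical, the
exact end rule between 75 and 80 is this package's declared convention.

LBD: the candidate region downstream of the DBD (whole sequence if none)
is semi-globally aligned to the reference LBD; the reference anchors
(helix-3 start + 11, helix-10 end) are mapped through the alignment, with
ties at candidate-side gaps resolved toward the interval interior. The
score is normalized by the reference LBD self-score.

Verification replaces unavailable external NR predictors with rules:
DBD + LBD with normalized score ≥ θ₁ = 0.4 → NR; no DBD but best-scoring
reference is an NR0B receptor with score ≥ θ₂ = 0.5 → NR0B candidate
(stricter because that path lacks the motif evidence); otherwise rejected.
Random decoys score ≈ 0 or below, diverged true genes ≥ ~0.5, so the
thresholds sit in a wide empty margin.

## Cataloguing

Candidates from all hit sets are unioned and deduplicated on exact residue
identity (lexicographically smallest id kept, merges reported). Ortholog
assignment scores each verified candidate against every template as the
mean of DBD and LBD percent similarities (template side as denominator;
LBD-only where either side lacks a DBD); best template wins, near-ties
(top two within 1% relative) are flagged ambiguous rather than silently
resolved, and a reciprocal flag marks candidates that are their template's
best hit within the species — the offline stand-in for curated orthology
annotations. The presence matrix counts copies per (species, receptor) in
manifest order; paralog counts are `Σ max(copies − 1, 0)`.

## Conservation statistics

Profiles: for each column where the reference row has a residue, the raw
value is the fraction of other rows with the identical residue (gaps count
as mismatches); the windowed value averages the raw profile over a
10-residue window clamped (not padded) at the edges. Grouping of one
receptor's cross-species LBD similarities: group 1 if every species ≥ 90%,
else group 3 if every species < 85%, else group 2 — precedence 1, 3, 2
resolves the overlap between the verbal ranges, and the max-based group-3
rule is a declared convention. When paralogs exist, the species is
represented by its best-scoring copy ("best-alignment ortholog").

## Phylogenetics

p-distances use pairwise deletion by default (complete deletion
available); a pair with zero comparable sites is an error. Poisson
correction `d = −ln(1−p)` (domain error at p ≥ 1). Neighbor joining
follows the Saitou–Nei Q-criterion with ties broken on the lexicographic
pair of smallest-leaf labels, negative branch estimates clamped to 0 (and
logged), and the final three nodes joined through a trifurcating root.
Bootstrap resamples columns with replacement (seeded), rebuilds with the
same builder, and supports each internal edge of the original tree by the
percentage of replicates containing its unrooted split; replicates whose
distances saturate are counted as not containing the split. Newick output
rounds lengths to 6 decimals and stores supports as internal labels.

Maximum-likelihood trees are out of scope; the distance reading of the
"Poisson model" is the one implemented.

## Problem sizes and determinism

The default benchmark used by the test suite and the worked example is 48
templates × 12 species with 100 decoys per species (~1,800 proteins), tree
bootstraps at B = 100 in tests (B = 1000 is the config default), and
20-replicate phylogeny-recovery experiments on 8-taxon trees with ~1,100
concatenated LBD columns — sizes chosen so the whole suite runs in minutes
on one core while every statistic retains a comfortable margin. All
randomness flows from the run seed (template generation, evolution, decoy
sampling, bootstrap); a fixed seed reproduces byte-identical artifacts,
which the test suite asserts by hashing the output directory.

## Known limitations

* No indel evolution — boundary recovery is exact by construction; real
  orthologs with insertions near domain edges would show ±few-residue
  boundary error, bounded by the alignment mapping.
* The Karlin–Altschul K is configured, not estimated; absolute E-values
  are therefore only internally comparable.
* One-hit seeding with exact k-mers loses sensitivity beyond ~50%
  divergence; the calibration-margin mechanism does not compensate for
  seeds that never fire.
* The three-group classification and the DBD end rule encode declared
  conventions where the surveyed protocol left details unstated.
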