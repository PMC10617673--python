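# Methods

This note documents the models, rules, numerical choices and known
limitations of `catchscan`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Capture detection

**Distance rule.** For a two-chain model, the pairwise Euclidean
Cα–Cα distance matrix D (substrate × receptor) is computed with
`scipy.spatial.distance.cdist`. A substrate residue qualifies as a seed
when its minimum distance to each of the two anchor ranges is below the
cutoff. Defaults: anchors 148–157 and 279–286 in receptor author
numbering (assumed to match the UniProt numbering of the receptor
sequence that was folded), cutoff 5.5 Å — just above the < 5 Å
inter-strand distances typical of β sheets.

Seeds must form runs of at least `min_run = 2` consecutive author
numbers ("sequential residues", plural). Sequentiality of the receptor
side (*j*) is not checked explicitly: anchor ranges are only 8–10
residues long and a substrate residue within 5.5 Å of both at β-sheet
geometry cannot match them non-sequentially in practice; `min_run` and
the cutoff are both parameters of `CaptureParams` should a different
operationalization be needed.

**Secondary structure.** A minimal, self-contained Kabsch–Sander
assignment: the amide hydrogen is reconstructed 1.0 Å from N along the
previous residue's C→O direction (prolines and segment-first residues
have none); the electrostatic bond energy is
E = 0.084·332·(1/r(ON) + 1/r(CH) − 1/r(OH) − 1/r(CN)) kcal/mol with a
bond declared below −0.5 kcal/mol; parallel/antiparallel bridges follow
the standard two-pattern definitions, and only residues in ladders of at
least two consecutive bridges are coded "E" (an isolated bridge is
coded '-'). A simple α-helix detector (two consecutive i→i+4 turns)
yields "H"; "E" wins any conflict. Assignment operates on all chains of
a model jointly, because the substrate strand's bridge partners are in
the receptor chain. Pairs with any of the four distances ≤ 0.5 Å
(steric clash) are treated as unbonded; Cα pairs ≥ 9 Å apart are
pre-filtered.

Segment termini (chain ends, and the flanks of any physical chain
break, detected as C–N distance > 2.5 Å or non-consecutive numbering)
are coded '?' — they cannot be assigned because the first residue of a
segment has no reconstructable amide H. `propagate_terminal_E` then
resolves every terminal '?' to "E" iff its inward neighbour is "E",
else '-'. The synthetic receptor consists of two anchor segments plus
an isolated reference residue, so '?' legitimately appears at internal
segment boundaries as well as chain ends.

**Refinement.** Three literal steps: intersect seeds with E-coded
residues (empty ⇒ no capture); expand the survivors by ±7 positions in
sequence space, clipped to chain bounds, and intersect with "E" again;
report the longest contiguous "E" run, preferring the most N-terminal on
ties (a deterministic convention). Over a ranked model set, a substrate
is called captured iff ≥ 1 model yields a strand; the representative
interval comes from the lowest (best) qualifying rank, the highest-
confidence prediction.

## Annotation statistics

**Facing.** A strand residue is raw-called inward when its Cβ is
strictly closer than its Cα to the Cα of receptor residue 309 (a
residue central to the Catch-domain core; glycines, having no Cβ, are
skipped). Because side chains along a β strand alternate sides but
terminal residues are rotationally variable, raw calls are reconciled:
whichever of the odd or even 1-based position sets (N→C within the
strand) overlaps the raw calls better becomes the inward set wholesale;
an exact tie is an error requiring an explicit override.

**Enrichment.** For depth *n* from either terminus, only strands of
length ≥ 2n contribute (each strand residue is counted at most once
across the two sides), and observed frequencies are divided by the
amino-acid background pooled over the substrate sequences. Flanking
frequencies use the residue immediately before/after the strand,
skipping strands that touch the protein's termini. Σₐ ratio(a)·bg(a) = 1
holds per (side, depth) by construction; a zero-background amino acid
observed in strands yields an infinite-ratio sentinel with a warning.

**Contrasts.** Both the hydrophobicity contrast (strand mean vs
rest-of-substrate mean per substrate) and the pLDDT contrast (captured
region vs rest in the receptor-free monomer) are two-sided paired
Student t-tests implemented from the closed form (t = mean(d)·√n/sd(d),
df = n−1; all-zero differences give t = 0, p = 1); `scipy.stats.ttest_rel`
serves only as an independent oracle in the tests. The default
hydrophobicity table is the pH-7 normalized scale of Monera & Hodges
(F = 100 … D = −55); any scale can be injected, and no result in this
package depends on the specific values. The pLDDT contrast reports the
captured-minus-rest sign convention: negative = captured region
predicted less confidently (more disordered).

## GPS screen analysis

Counts arrive in long format (gene, barcode, condition, bin, reads);
barcodes are summed to gene level before anything else. Depth
normalization scales each bin column to the mean library size
(total-count normalization, the simplest reading of "corrected for
sequencing depth"; configurable off). PSI = Σ Rᵢ·i over the six bins of
one condition, ΔPSI = PSI_treatment − PSI_control, and the
destabilization filter keeps genes with ΔPSI strictly below −0.5,
ordered most-destabilized first. Genes with zero reads in a condition
get a missing PSI and are excluded from filtering with a logged count.

## Synthetic data

**Sheets.** Backbones are built atom-by-atom (NeRF construction) from
ideal bond lengths/angles at extended dihedrals (φ = −139°, ψ = +135°,
ω = 180°); Cβ atoms sit at the ideal tetrahedral position, so facing
alternation is geometrically exact. The substrate strand is placed
canonically (axis along x, carbonyls toward the partners); each anchor
strand is a flipped copy placed at ±spacing (default 4.8 Å, valid range
4.0–5.5 Å) whose registry (flip choice, axial and pleat offsets) is
fixed by a deterministic coarse-then-fine grid search maximizing,
lexicographically, the number of Kabsch–Sander bonds, the number of
substrate residues with a nearby anchor Cα (aligned pleats — a true
sandwich), and bonded energy. Registry calibration is cached per
(spacing, lengths, side, orientation) and makes generated sheets satisfy
the very hydrogen-bond criteria the detector tests, which is the point
of the fixture. Substrate flanks are built α-helical; the take-off
dihedrals at each strand–flank junction are chosen from a small
candidate set to maximize clearance from the anchors while keeping the
junction residue un-E-coded, so flanks neither collide with the sheet
nor extend the planted strand. Anchors span exactly the scanned ranges
(10 and 8 residues): planted strands up to length 8 are spanned by both
anchors and are recovered exactly; longer strands lose unbondable end
residues, so recovery there is defined as midpoint containment. The
receptor also carries a single isoleucine (number 309) 10 Å below the
sheet plane as the facing reference; ground truth (interval, inward
set, parity) is recorded alongside every generated complex. Decoys fold
the same substrate sequence as an α helix docked ≥ 8 Å from both
anchors (or, optionally, within 5.5 Å of exactly one anchor, to
exercise the both-anchors requirement). All structure output is
standard PDB via gemmi with pLDDT in the B-factor column; generation is
byte-deterministic for a given spec and seed.

**Screens.** The generator mirrors the experiment's two stages. Cells:
each gene's control bin distribution is a point mass at bin 6 shifted
down by a per-gene stability offset drawn from an end-weighted mixture
over [−5, 0] (atoms of 1/12 at each end, uniform in between) — chosen
so the pooled control occupancy of the six bins is uniform, exactly what
FACS gating enforces; offsets are clipped to keep the gene's planted
effect feasible (the two fractional shifts compose through their
floors). The treatment distribution is the control shifted along the
bin axis by the planted ΔPSI, by moving probability mass with exact
interpolation between integer shifts, so the expected PSI difference
equals the planted effect exactly; shifts that would push mass outside
bins 1–6 are an error. Sequencing: each bin is its own sample with a
fixed read depth (reads_per_gene·n_genes/6, scaled by optional per-bin
depth factors), drawn multinomially from the bin's cell composition —
so total-count depth normalization removes exactly the planted depth
unevenness. Under this generator the ΔPSI estimator is unbiased at the
default depth (verified to |bias| < 0.05 in the acceptance tests); a
strong treatment-side occupancy drift (a large fraction of strongly
destabilized genes) would reintroduce a small compositional bias, as it
would in the real assay.

## Problem sizes in the checks

The acceptance tests run: a 6,000-gene screen with 508 planted
destabilized genes at 500 reads/gene; a 20-point capture grid (strand
lengths 4–12 × spacings 4.6–5.0 Å) plus an 11-complex decoy family;
1,000-replicate null calibrations of the paired tests at cohort sizes
6–8; and bias/RMSE checks at 2,000 and 300 genes. These sizes keep the
suite fast while leaving every rule exercised at full fidelity.

## Known limitations

- The secondary-structure module implements only E/H/'-' (plus internal
  '?'), not the full DSSP alphabet; isolated bridges ('B' in DSSP) are
  deliberately coded '-' under the "E coding" reading. Agreement with
  any particular external DSSP binary is fixture-level, not bitwise.
- Role assignment uses best ungapped identity; chimeric or highly
  repetitive chains could in principle tie (an explicit override is the
  escape hatch).
- The idealized sheets have perfect geometry; real predicted models
  show twist, fray and imperfect registry, so passing the synthetic
  grid demonstrates correctness of the rules, not robustness to every
  structural pathology.
- The screen simulator plants two-bin (sharp) reporter distributions;
  broader per-gene distributions would raise per-gene PSI variance but
  leave the estimators' structure unchanged.
- PDB input only (no mmCIF); first MODEL block and first altloc only;
  heteroatoms, waters and ligands are ignored.
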