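# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## CATS topological pharmacophore-pair descriptors

**Model.** A molecule is reduced to its hydrogen-suppressed graph. Each heavy
atom receives zero or more pharmacophore feature types by SMARTS rules:
donor D (O/N bearing H), acceptor A (any O; N without H retaining a lone
pair, excluding quaternary and amide N), positive P (formal positive charge,
basic aliphatic amines, guanidine), negative N (formal negative charge,
carboxylic/sulfonic/phosphonic acid oxygens), lipophilic L (C or S whose
heavy neighbors are all C or S, at least one heavy neighbor required), and
aromatic R (toolkit aromaticity flag). CATS1 uses {D,A,P,N,L} and never
assigns R, so aromatic carbons can count as lipophilic; CATS2 adds R and
excludes aromatic atoms from L. For every unordered type pair and every
shortest-path distance d ∈ {0,…,9} the descriptor counts atom pairs (i ≤ j)
carrying the two types, each atom pair contributing at most once per type
pair; the d = 0 bin counts single atoms carrying both members of a
heterotypic pair. This gives 15 × 10 = 150 (CATS1) or 21 × 10 = 210 (CATS2)
nonnegative integers. Types scaling divides each pair block by
λ(T1,T2) = occurrences(T1) + occurrences(T2) (twice the count for homotypic
pairs), with 0/0 ≡ 0.

**Decisions and switches.** The original implementation is proprietary and
its exact SMARTS, self-pair handling and distance binning are not public.
The shipped rule table is a reconstruction from the published feature-type
definitions and common pharmacophore conventions; it is YAML-overridable
(`cats.load_rules`) and its hash is recorded in every descriptor sidecar so
alternative typings remain comparable. The undocumented conventions are
exposed as switches with these defaults: bins cover d = 0..9
(`binning="d0"`; `"d1"` maps bins to 1..10) and heterotypic self pairs are
counted (`count_self_pairs=True`). The defaults reproduce the canonical
150/210 dimensionalities. Atom pairs spanning disconnected fragments
(infinite distance) are never counted. Aromaticity follows the toolkit's
default perception model.

**Invariants tested.** Atom-renumbering invariance (20 random SMILES
renderings × 50 molecules), raw-count conservation against a brute-force
double loop, zero-pattern preservation under λ scaling.

## Ranked retrieval

Metric descriptors (CATS) are compared by Euclidean distance, bit
fingerprints (Morgan radius 2/2048 bits, MACCS keys, RDKit path fingerprint)
by the Tanimoto coefficient. Rankings are deterministic: best score first,
ties broken by candidate id ascending (the choice is arbitrary but
reproducible). The Tanimoto of two empty bit sets is defined as 1.0 — two
featureless objects are indistinguishable — and logged as a degenerate case.

## Retrospective benchmark

For each target with at least `min_actives_per_target` (default 20)
annotated ligands, every ligand serves as a query against all remaining pool
compounds; its co-ligands are the actives (multi-target compounds are active
in each of their targets' runs). Early enrichment is scored with
BEDROC(α): with N candidates, n actives at ranks r_i and R_a = n/N,

    RIE    = (1/n) Σ exp(−α r_i/N) / [(1/N)(1 − e^{−α})/(e^{α/N} − 1)]
    BEDROC = RIE · R_a sinh(α/2) / (cosh(α/2) − cosh(α/2 − αR_a))
             + 1 / (1 − e^{α(1−R_a)})

bounded in [0,1]. The default α = 160.9 is the root of
(1 − e^{−αz})/(1 − e^{−α}) = f at z = 0.01, f = 0.8 — the top 1 % of the
list carries 80 % of the score mass — computed by bracketed root finding
(`alpha_for_contribution`, tolerance 1e-6). Scaffold-hopping potential is
r = s/n: distinct Murcko scaffold keys s among the n actives retrieved in
the top ⌈z·N⌉ entries (ceiling guarantees a nonempty cut). Murcko
frameworks retain atom and bond types; acyclic molecules pool into one empty
scaffold class. Queries are excluded from their own pool; the query's
scaffold is not excluded from the s count.

Descriptor families are compared by pairwise one-sided Wilcoxon rank-sum
tests on the per-query score distributions (pooled over targets by default;
a `per_target` aggregation switch averages within target first, since it is
not documented which convention the original analysis used). Ward clustering
runs on the symmetrized distance d(i,j) = 1 − 2·min(p_ij, p_ji), which maps
indistinguishable distributions (both one-sided p ≈ 0.5) to d ≈ 0 and fully
separated ones to d ≈ 1; this transform is our choice and is recorded in
output metadata. Violin plots of the distributions are a plotting
convenience over the result tables (inclusive quantile definition).

## Toroidal self-organizing map

Online Kohonen training on a rectangular grid with wrap-around (toroidal)
topology: default 16×10 = 160 cells, 10^6 cycles, initial Gaussian
neighborhood radius 8. Per cycle one input row is drawn (seeded RNG), the
best-matching unit is the codebook row at minimal Euclidean distance (ties
to the lowest flattened cell index), and every codebook row moves by
η(t)·exp(−d²/2σ(t)²)·(x − w) with grid distance d measured on the torus.
The reference tool's schedules and initialization are not published, so
standard reproducible defaults were adopted: codebook initialized by
sampling input rows; σ decays linearly radius0 → 0.5 and η linearly
0.5 → 0.01 over the cycles; everything is determined by the seed.
Equivalence with maps from the original tool is therefore not claimable —
only qualitative behavior (separation of dissimilar compound sets,
density structure) is.

Tests run the map at desk scale (10³–10⁴ cycles, grids of 12–40 cells);
10^6 cycles remains the documented production default. Online SOM training
converges slowly as a quantizer: beating the sampled-row initial codebook's
quantization error on easy data takes ~5·10⁴ cycles at 40 cells, which the
quantization test uses.

## Target prediction by SOM co-clustering

The SOM is trained on the union of annotated references and query compounds
(e.g. an enumerated virtual library) in CATS2 space. A query's candidate
targets are the annotations of references sharing its cell — a conservative
application domain; queries in cells without annotated references get no
predictions. Per (query, target) the score is the minimal Euclidean CATS
distance to a co-clustered ligand of that target (nearest neighbor: the
assumption-lightest reading of "similarity to known ligands"). The score is
converted to an add-one empirical p-value
p = (1 + #{null ≤ score}) / (1 + M) against a null of up to `max_pairs`
(default 10^6, seeded subsample) Euclidean distances between reference pairs
with disjoint target sets. The null is global rather than per-target:
desk-scale reference sets make per-target backgrounds too sparse to
estimate reliably, so one shared background over all inter-target pairs is
the default.
Library-level profiles average p per target over the compounds predicted for
it (strictly below the threshold to be reported); a switch can average over
the whole library instead, counting unpredicted members at p = 1. Joint
ranking for a target pair keeps compounds predicted for both and sorts by
the worst-case (maximum) of the two p-values — both predictions must be
confident.

**Known limitation — the p-values are anti-conservative.** The per-target
score is a *minimum* over the k co-clustered ligands of that target, and the
top-ranked prediction further minimizes over candidate targets, while the
null distribution holds *single-pair* distances. Even for signal-free
queries this min-of-k selection makes small p-values far more frequent than
uniform (≈ 1 − 0.95^k at p < 0.05); the acceptance suite measures ≈ 0.55–0.6
instead of ≤ 0.10 on label-randomized desk-scale fixtures, essentially
independent of SOM grid size. The p-values are therefore a relative
prioritization score, not a calibrated type-I error estimate; any
implementation pairing nearest-neighbor scores with a single-pair null
inherits this optimism.

## Synthetic data

`fixtures.generate_collection` emulates a curated annotated compound
collection at desk scale. Each target family decorates a few ring scaffolds
(drawn from a ~30-entry vocabulary of common ring systems, including the
imidazo[1,2-a]pyridine core typical of three-component libraries) with side
chains from a family-characteristic motif pool (donor–acceptor chains,
aromatic-plus-basic-amine, ether/ester acceptors, acidic chains, amides), so
ligands of one target are close in CATS space yet spread over several Murcko
scaffolds; decoys combine arbitrary scaffolds with arbitrary motifs. All
structures are valence-legal and round-trip through canonical SMILES; all
randomness flows through one seeded generator per call. The default
benchmark fixture (3 targets × 25 ligands over 4 scaffolds + 100 decoys)
mirrors the structure — not the scale or chemistry — of a real reference
collection: it has planted, linearly separable pharmacophore signal, no
activity cliffs, no assay noise, and far fewer scaffolds per target than
real data. Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted signal, not screening performance on real
collections. Building-block sets for enumeration carry marked attachment
points compatible with the trivial fragment-joining assembler; the
reaction-transform assembler encodes the Groebke–Blackburn–Bienaymé
coupling and reproduces the two published reaction products and their
HRMS-calculated [M+H]+ values.

## Monoisotopic masses

[M+H]+ = Σ most-abundant-isotope masses + 1.007276 Da (proton mass, not the
hydrogen atom mass — the convention that reproduces published HRMS-ESI
calculated values to four decimals), rounded to 4 decimals on output.

## Numerical and degenerate-input choices

* Root finding brackets α in (10⁻⁶, 10⁴); no root is a fatal error.
* BEDROC requires ≥ 1 active and ≥ 1 inactive; degenerate queries are
  skipped with a warning in benchmark runs.
* Rank-sum tests on two identical constant distributions record p = 0.5 with
  a warning; Ward distances are clipped at 0.
* Descriptor failures in batch computation yield an all-zero row plus a
  logged warning rather than aborting the batch.
* Empty scaffold keys ("" for acyclic molecules) count as one scaffold class.
* SOM BMU ties resolve to the lowest flattened cell index; `cycles=0`
  returns the initial codebook, making initialization testable.

## Desk-scale test sizes

The test suite runs stochastic properties at reduced problem sizes chosen to
finish in minutes on one CPU: SOM separation uses 8×5 grids with 10⁴ cycles
over 100 seeds; planted-target recovery uses 3 × 18-ligand families with
4×3 maps and 2×10³ cycles over 100 seeds; benchmark fixtures use 2–3 targets
with 8–25 ligands. Production defaults (16×10 grid, 10⁶ cycles, α = 160.9,
top 1 %, ≥ 20 actives per target) are unchanged by testing and are what the
CLI uses unless overridden.
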