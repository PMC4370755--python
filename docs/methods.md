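# Methods

This note records the models behind `condiv`, the assumptions they make, the
numeric choices that were genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Column contrast model

**Partition.** A master alignment with hierarchical group labels defines a
tree of nested contrasts. At each node, the foreground is the node's member
set and the background is its within-parent complement (for a top-level
family: the rest of the superfamily; for a subfamily: its sibling
subfamilies). Partitions are entirely label-driven; the package does not
re-assign sequences to groups.

**Sequence weighting.** Henikoff position-based weights: in a column with r
distinct residue types, a sequence showing residue a (occurring s_a times)
contributes 1/(r·s_a); a sequence's weight is the mean of its contributions
over its own non-gap columns, rescaled to mean 1. Weights are computed on the
*unique* rows and split equally among identical copies. The split is what
makes the correction exact: adding duplicates of any sequence redistributes
its mass without moving any weighted column frequency (the package treats
this as an invariant and tests it to 1e−9). Gaps and unknown residues (X,
and the non-standard codes B/Z/U/O/J normalised to X on input) carry no
weight and are excluded from effective totals.

**Ball-in-urn score.** For a column and pattern set R, weighted counts are
rounded to integers and the upper hypergeometric tail P(X ≥ k_F) is computed
in log space (log-gamma + logsumexp). The rounding step means the test
operates on effective counts; with mean-1 weights these are close to raw
counts, and the hypergeometric law is then exactly the permutation null for a
fixed R (foreground membership exchangeable given the pooled column
composition).

**Pattern selection and the selection adjustment.** The set R is grown
greedily: seed with the foreground-majority residue, then repeatedly add the
candidate residue (foreground frequency above background frequency) that most
decreases the *adjusted* p-value, stopping when no addition helps.
The adjustment multiplies the raw tail by the number of nonempty residue sets
of size up to |R|, `sum_{j<=|R|} C(20, j)` — a Bonferroni charge for the sets
the search could have reached. This choice is load-bearing twice over.
First, calibration: the raw tail refers to one pre-specified set, while the
search optimises over sets; without the charge, the procedure flags
false-positive columns in essentially every null data set (measured: 100% of
null replicates; ~14% of null columns individually), whereas with it the
family-wise false-positive rate sits at or below the nominal 5%. Second,
parsimony: the charge grows steeply with |R|, so the greedy stops adding
weakly-enriched residues (null pattern sets are then almost always
singletons), and a compact conserved pattern always beats the sprawling
complement "anti-pattern" that the mirrored contrast at a sibling node would
otherwise produce.

**Significance and ranking.** Columns whose foreground effective coverage is
below 50% are not scored (they belong to the insert analysis instead, which
deliberately looks at exactly such columns). Eligible columns are cut by
Bonferroni at family-wise α = 0.05 over the eligible-column count (a
`top_k` override reports a fixed display set instead); ranked positions are
sorted by ascending adjusted p with column-index tie-breaks. Heights are
−log10 of the adjusted p.

**Exclusive hierarchical assignment.** A column genuinely conserved in one
subfamily also contrasts at the family node (at ~half the conservation) and
at its sibling (every other residue is enriched there by depletion). Reported
significance is therefore assigned per column to a single node: nodes where
the pattern is conserved in the foreground (pattern frequency ≥ 0.7) and
divergent in the background (≤ 0.3) are preferred, and among those the
smallest adjusted p wins (ties: shallower node, then name). The two frequency
gates encode what "pattern position" means — conserved here, strikingly
different there — and the size-dependent selection charge settles the
remaining parent/child and sibling mirror ambiguities. Both gate values are
parameters of `subfamily_contrasts`.

**Insert detection.** A column qualifies when weighted foreground non-gap
occupancy ≥ 0.5 and weighted background gap fraction ≥ 0.9. Maximal
qualifying runs of ≥ 2 columns are reported, after merging runs separated by
fewer than 2 columns; each run is scored by the same ball-in-urn law on
present-vs-gap counts at its most contrasted column. The occupancy/gap
thresholds deliberately differ from the pattern-coverage rule: inserts are
defined by the background being *absent*, patterns by both sets being
present and different.

## Docking-motif scanner

The docking consensus ψ(1–3) X(3–7) Φ-X-Φ is scanned with ψ = {K, R}
(histidine excluded: often uncharged at physiological pH) and
Φ = {L, I, V, F, M}; both sets are parameters, since the consensus defines
the classes chemically, not as fixed residue lists. Every start with a valid
parse is reported, each start contributing its leftmost-longest parse (ties
toward the longer basic run); parses whose hydrophobic triplet is already
claimed by an earlier, longer match are folded into it, so one basic run
yields one match while genuinely distinct overlapping occurrences are all
kept. Every reported interval re-validates against an independent regular
expression in the test suite.

## Structural interaction mapping

Structures are read from PDB files (first model, altloc blank/'A', HETATM
excluded unless ligands are requested). Alignment columns map to chain
residues through a global pairwise alignment of the reference row (gaps
removed) against the chain sequence (match +2, mismatch −1, gap open −5,
extend −1; identity below 30% over aligned pairs is rejected as a mismatched
reference).

Interaction criteria are standard geometric literature values, all exposed in
`RunConfig`:

| type        | criterion                                                        | default |
|-------------|------------------------------------------------------------------|---------|
| salt bridge | min distance, basic side-chain N (Arg NH1/NH2/NE, Lys NZ, His ND1/NE2) to carboxylate O (Asp OD1/OD2, Glu OE1/OE2) | ≤ 4.0 Å |
| H-bond      | donor–acceptor heavy-atom distance AND antecedent–donor–acceptor angle | ≤ 3.5 Å, ≥ 120° |
| van der Waals | any heavy-atom pair, residues ≥ 2 apart in sequence            | ≤ 4.5 Å |
| CH–π        | carbon to aromatic ring centroid (Phe/Tyr/Trp/His)               | ≤ 4.5 Å |

The hydrogen-free H-bond criterion is used because crystal structures rarely
resolve hydrogens. Interactions become edges of an undirected residue graph;
named regions (docking groove 119–134, αE 124–144, β7–β8 159–163, CD site
313–316, αC 59–78, C-tail 310–356, in the p38α reference numbering) are
shipped as a configurable map, and coupling between regions is the shortest
path (fewest edges, lexicographic tie-breaks) between their member residues.
Interaction *energies* are out of scope: all criteria are geometric.

## Trajectory statistics

Superposition is the Kabsch algorithm: least-squares optimal proper rotation
(SVD with determinant correction, so mirror images keep a positive RMSD
rather than being reflected away). RMSF and the cross-correlation map first
superpose every frame onto an iterated mean structure (two mean–superpose
passes) over the selected atoms — Cα by default, with residue-range
exclusions for flexible termini — so global rigid motion does not masquerade
as internal fluctuation. Definitions, with dr_i(t) the deviation of atom i
from its time-mean position:

    RMSF_i  = sqrt(<|dr_i|^2>)
    DCCM_ij = <dr_i · dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)

Zero-variance atoms get zero off-diagonal DCCM entries (diagonal 1) with a
warning. H-bond/salt-bridge occupancy is the fraction of frames satisfying
the geometric criterion (distance, plus the angle when an antecedent atom is
given; a salt bridge is a distance-only specification); it is computed on raw
coordinates since internal distances and angles are rigid-motion invariant.

One numerical caveat is worth knowing: fitting the superposition on the same
atoms whose fluctuations are measured removes 6 rigid degrees of freedom from
3A, shrinking RMSF by roughly sqrt(1 − 2/A) and correlations accordingly. At
protein-like selection sizes (A ≈ 100 Cα) the bias is ~1%; at toy sizes
(A ≈ 10) it reaches ~10%. The verification runs therefore use 100-atom
selections for RMSF and 60-atom selections for DCCM.

## Synthetic-data generators

The generators produce inputs with the statistical structure the analysis
assumes, carrying their ground truth:

* **Alignments.** Per-column background distributions are Dirichlet(0.5)
  draws over the 20 residues (concentration 0.5 gives realistically skewed
  column compositions; configurable). Planted pattern columns state the
  *total* pattern-set frequency: members of the pattern's group draw a
  pattern residue with the stated conservation, everyone else with the stated
  background frequency, and non-hits redraw from the column distribution
  restricted to non-pattern residues. Insert intervals are present/absent per
  sequence (an indel is a sequence-level event): foreground sequences carry
  the interval with the stated occupancy, background sequences gap it with
  the stated gap fraction. Pattern columns inside planted insert intervals
  are rejected as inconsistent. The default study conditions are 200
  foreground / 600 background sequences over 150 columns, planted
  conservation 0.95 against background frequency 0.05 — a deliberately strong,
  desk-scale stand-in for a family-diagnostic column in a large curated
  superfamily alignment.
* **Trajectories.** Displacements are zero-mean multivariate normal per
  coordinate axis with covariance S_ij = ρ_ij σ_i σ_j, under which
  RMSF_i = σ_i√3 and DCCM_ij = ρ_ij exactly — which is what makes recovery
  falsifiable without running MD. Optional per-frame random rigid motion
  exercises the superposition; planted H-bond pairs place the acceptor at an
  exact inside/outside distance by seeded Bernoulli draws at the target
  occupancy.
* **Toy structures.** Minimal two-residue models with one interaction pair at
  an exact requested distance and otherwise ideal geometry, for threshold
  tests.

All generators are deterministic given their seed (same seed, byte-identical
output).

**What passing tests show — and do not.** The generators are i.i.d. across
sequences and frames: no phylogenetic correlation between sequences, no
substitution-model realism, no autocorrelated or anharmonic dynamics, no
solvent. Passing recovery tests therefore demonstrates the *estimators and
procedures* are correct under their own assumptions, not that real kinase
alignments satisfy those assumptions. In real master alignments,
phylogenetic clustering makes effective sample sizes smaller than sequence
counts; the Henikoff weighting mitigates but does not remove this, so
reported significances on real data are best treated as rankings.

## Verification problem sizes

The from-scratch verification (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) uses: an exhaustive hypergeometric sweep over all
integer cases with T ≤ 30 against exact rational enumeration (46,375 cases,
agreement to 1e−12); planted-pattern recovery and false-positive control at
the 200/600×150 study conditions (100 null replicates); hierarchical
assignment over 10 replicates; 10,000-frame trajectories for RMSF and
occupancy and 5,000 frames for DCCM. These sizes keep each quantity's
sampling error well inside its stated tolerance.

## Known limitations

* The contrast model scores columns independently; co-evolving column pairs
  are not modelled.
* Partitions are label-driven only; sequences with wrong or missing labels are
  not re-assigned (unlabeled sequences fall to the root with a warning).
* H-bond detection from crystal structures cannot see hydrogens; the
  heavy-atom criterion admits some geometrically plausible non-bonds.
* The column→structure mapping assumes the reference row and the chain are
  the same protein up to point differences and unresolved residues; large
  rearrangements will map poorly and are rejected only by the 30% identity
  floor.
* Trajectory readers cover multi-model PDB and plain XYZ tables; binary
  formats (DCD/XTC) are intentionally out of scope.
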