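# Methods

## Problem setting

Given a phosphatase with a set of experimentally known dephosphorylation
sites (the positive class) and a corpus of human protein sequences with pY
annotations, the task is to rank every annotated 11-mer pY window by its
plausibility as a peptide substrate, keep a high-confidence consensus,
filter by biological context, and vet docked phosphatase–peptide complexes
geometrically. All stages operate on user-supplied plain-text inputs (FASTA,
TSV, GMT, PDB); database retrieval is explicitly out of scope.

## Window model

Windows are 11-mers: five residues either side of a central pY. Sites closer
than five residues to a protein terminus are kept and padded with `-`
(blank), which is treated as the 21st alphabet symbol by the frequency
matrices and the classifier encoding, and contributes zero to the logo
score. How terminal sites were handled in the original protocol is not
recorded anywhere we know of; padding keeps the library complete and is the
choice made here. Windows containing `X` are dropped with a warning, since
no frequency information exists for unknown residues. Identical 11-mers are
collapsed into one window with merged `(protein, position, gene)` sources;
all downstream scores are functions of the sequence alone, so per-site and
per-window scoring coincide, and site-level verdicts map back through the
sources (a window passes if any source site passes).

Background ("negative") windows are taken around every tyrosine of proteins
that carry *no* pY annotation at all. This protein-level exclusion mirrors
the usual construction of a negative class from unannotated proteins; a
`site_level` flag restricts exclusion to the annotated positions for corpora
dense enough that whole-protein exclusion would discard too much.

## Scores

**Method 1 — information content.** Logo heights are f(i,j)·R_j with
R_j = log₂20 − (H_j + e_n) clamped at zero. The small-sample correction
e_n = 19/(2·ln2·n_j) uses the per-column count of non-blank residues and is
on by default (matching the common logo convention); both modes are tested.
A window's score is the sum of the heights of its residues over the ten
flanking columns.

**Method 2 — PSSM.** Positive, negative and total matrices are relative
frequencies over 21 symbols × 10 positions; the total matrix is built from
the pooled multiset, so column-wise total = w·positive + (1−w)·negative with
w the positive fraction. The published flow chart's exact combining formula
is not legible in the available text, so the default here is the log-odds
with total-matrix pseudocount

score(w) = Σ_j log₂[(f⁺(a_j,j) + α·fᵗ(a_j,j)) / (f⁻(a_j,j) + α·fᵗ(a_j,j))],

with α = 0.05. α shrinks both class frequencies toward the pooled
frequency, bounding the score for symbols unseen in one class; a symbol
absent from *all* data contributes zero. The term function is a pluggable
callable and the formula identifier (`log-odds-total-pseudocount-v1`) is
written into run manifests so results remain traceable if it is swapped.

**Method 3 — calibrated classifier.** A full phosphosite predictor with
disorder and k-nearest-neighbour features is deliberately not re-implemented.
The classifier here is a logistic-loss linear model on one-hot
(21 symbols × 10 positions) plus amino-acid-composition features. Negatives
are split (seeded shuffle) into a training half and a calibration half; the
decision threshold is the order statistic of calibration scores at the
target specificity (default 0.95), so at most 5% of fresh negatives pass in
expectation. Training requires ≥ 20 windows per class. Randomness in the
whole scoring stack is confined to this split; the seed is a required
argument. An import adapter (`read_external_scores`) lets externally
computed per-peptide scores stand in for the built-in model.

**Consensus.** Records are ranked per method, descending by score with
lexicographic peptide order breaking ties (deterministic; the alternative of
including all tied records at the cutoff is not used). A record is in the
consensus iff rank ≤ ⌈q·N⌉ for all three methods; q defaults to 0.10. The
consensus set is by construction a subset of each method's top-q set and
monotone in q.

## Biological filters

A candidate gene passes if (a) it is a known substrate of the anchor
phosphatase or of any phosphatase whose substrate set intersects the
anchor's, or (b) it co-occurs with the anchor's gene in at least one pathway
of at least one supplied collection. Reading "same KEGG and PID pathways" as
a disjunction across collections is the default; a strict mode requiring
co-membership in every collection sits behind
`require_all_collections=True`. Matching is gene-level and case-normalised.
The substrate table is not restricted to a phosphatase family — any entry in
the user's table counts, and users who want PTP-family-only relatedness
simply restrict the table. Under the default mode the filter is monotone:
adding substrates or pathways never turns a pass into a fail.

## Pose criteria

Thresholds that were applied by eye in the original manual inspection are
made explicit here:

* **(i) pY in the catalytic site** — distance from the pY phosphorus to the
  centroid of the P-loop Cα atoms (residues 214–221 on the phosphatase
  chain, configurable) ≤ 7.0 Å, inclusive. The 7 Å default spans the pocket
  depth plus docking slack.
* **(ii) N→C orientation** — angle between the pose's Cα(pY−2)→Cα(pY+2)
  vector and the reference peptide's < 90°, strict; falls back to pY±1 for
  short peptides. Several references may be supplied; orientation is then a
  majority vote after superposing each reference onto the primary one.
* **(iii) hydrogen bonds** — heavy-atom donor–acceptor distances ≤ 3.5 Å,
  inclusive (poses typically lack hydrogens, so no explicit H geometry is
  assumed; an optional donor–acceptor–antecedent ≥ 90° angle term can be
  enabled). Bond 1: Asp-48 OD1/OD2 to backbone N of pY. Bond 2: the same
  carboxylate to backbone N of pY+1. Bond 3: Arg-47 backbone N to backbone O
  of pY−2. A missing atom makes that bond absent with a recorded reason,
  never an error.

A pose is accepted iff (i) and (ii) hold and ≥ 2 of the 3 bonds form.
Superposition is Kabsch (SVD with determinant correction, proper rotation
guaranteed) on phosphatase Cα atoms paired by residue number, ≥ 3 required;
evaluation is therefore invariant to any global rigid motion of the pose.
Phosphotyrosine is recognised by residue name (PTR by default, extensible).
Docking itself is upstream and out of scope; the module consumes poses.

## Mass arithmetic

Monoisotopic mass = Σ residue masses + H₂O (18.010565) + 42.010565 per
N-acetyl − 0.984016 for C-amidation + 79.966331 per phospho; average masses
use the corresponding standard-atomic-weight table. Constants are hard-coded
from the IUPAC tables and cross-checked against an independent mass library
in the test suite. Synthesis tables conventionally quote "calculated MW" as
the integer part of this monoisotopic value; `calculated_mw` applies the
floor while raw masses are always reported. Two of the eight published
synthesis peptides (IEDPpYpYGNDSD printed as 1485, computed ≈ 1487.45;
KKKKpYPKK printed as 1296, computed ≈ 1167.69) are inconsistent with this
arithmetic under their printed sequences — most plausibly typesetting or
sequence-length discrepancies — and are documented exclusions from the mass
validation.

## Synthetic data

`MotifSpec` plants a position-specific motif into otherwise random
proteins. The default motif is an acidic N-terminal stretch with a
hydrophobic −1 and E/V/L/P-flavoured C-terminal flank (echoing known
substrate peptides such as EEEDIpYEVLPD), each motif position drawing from
its preferred residue set with probability 0.75 and from the background
otherwise. Background residues are uniform over the 20 amino acids by
default; a human-proteome-like frequency preset ships as constants. Default
condition sizes: 50 planted sites, 450 background-class (decoy) annotated
sites and 150 unannotated background proteins of length 60–120 for the
query proteome; training proteomes emulate a curated
dephosphorylation-site collection and therefore contain planted sites only
(no decoys). Each annotated site sits on its own protein with full flanks,
so no padding enters the synthetic positives. Everything is deterministic
given the seed.

What the generator does *not* emulate: real amino-acid correlation
structure, homologous sequence redundancy, annotation noise, and the actual
PTP1B substrate motif beyond its acidic character. Passing the recovery
tests therefore shows that the pipeline's machinery ranks a planted signal
correctly under the stated noise model, not that it reproduces the original
database-dependent candidate lists, which depended on 2016 snapshots of the
source databases.

The toy pose generator builds an idealised phosphatase fragment (Arg-47,
Asp-48 with its carboxylate, a slightly twisted glycine P-loop at residues
214–221) and a 5-residue peptide whose relevant atoms are placed ≥ 0.5 Å
inside or outside each criterion's threshold according to boolean flags.
Geometric realism is out of scope; only the criteria geometry matters, which
is what makes exhaustive 32-combination enumeration of the accept rule
possible.

## Problem sizes and numerical choices

Tests and the recovery study run at library size 500 (50 planted + 450
decoys) with 5 seeds, large enough for the binomial tolerances used and
small enough to keep the suite fast. Classifier calibration is checked over
10 seeds with 300-window hold-out sets against 0.05 + 2·SE. Score-oracle
agreement is asserted to 1e−9, superposition against an independent
quaternion (Horn) solution to 1e−6, and rigid-motion invariance to 1e−6 in
Å/degrees. Ties in ranking are resolved lexicographically; degenerate logo
columns (all blank) carry zero information; empty training classes are
errors, not silent defaults.

## Known limitations

* The PSSM combining formula is a documented default, not a reconstruction
  of the original flow chart's (illegible) expression.
* The classifier is a linear stand-in with the same calibration contract as
  the original tooling, not a reimplementation of it.
* Gene-level (not isoform-level) identity in the filters.
* Single-model PDB input only; no mmCIF.
* Counts tied to 2016 database snapshots (library size 4931, 139-peptide
  consensus, 44 filtered candidates, specific ranks) are inherently
  irreproducible from scratch and are not validation targets.
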