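# ptpscout

Tools for discovering phosphotyrosine (pY) peptide substrates of protein
tyrosine phosphatase 1B (PTP1B, gene *PTPN1*), and, more generally, of any
phosphatase with known dephosphorylation sites.

Protein tyrosine phosphatases remove phosphate from pY residues, but far
fewer phosphatase substrates than kinase substrates are known. A cheap route
to new substrate peptides is computational: collect every known pY site on
human proteins as an 11-mer peptide window (5 residues, the central pY, 5
residues), score each window for similarity to the phosphatase's known
dephosphorylation sites, keep the peptides that all scoring methods agree
on, discard biologically implausible source proteins, and finally check that
docked phosphatase–peptide poses satisfy the catalytic-site geometry.
`ptpscout` implements that protocol end to end for users who bring their own
sequence, annotation, substrate and pathway tables (nothing is downloaded),
plus a synthetic-data generator that emulates the statistical structure of
the problem for testing and calibration.

## What it computes

**Library construction** (`sequence_library`). Non-redundant 11-mer pY
windows from FASTA + site annotations; background windows around every
tyrosine of proteins with no pY annotation. Terminal windows are padded with
`-` (blank), the 21st symbol of the scoring alphabet.

**Three scores per window** (`seq_scoring`), with positives = the
phosphatase's known dephosphorylation-site windows and negatives = the
background windows:

1. *Information-content score*: sum over flanking positions j ∈ {−5…−1, 1…5}
   of the sequence-logo height f(i,j)·R_j, where
   R_j = log₂20 − (H_j + e_n) is the column information in bits,
   H_j the column entropy, and e_n = 19/(2·ln2·n) the small-sample
   correction (on by default).
2. *PSSM score*: from positive, negative and pooled-total frequency matrices
   (21 symbols × 10 positions), the per-position log-odds with
   total-matrix pseudocount,
   Σ_j log₂[(f⁺ + α·fᵗ)/(f⁻ + α·fᵗ)], α = 0.05. The combining formula is
   pluggable and its identifier is written into every manifest.
3. *Classifier score*: a logistic-loss linear model on one-hot (21×10) +
   composition features, with its decision threshold calibrated on held-out
   negatives so that specificity ≥ 95%. An adapter accepts externally
   produced score files, so a full-featured site predictor can be slotted in.

**Consensus**: a peptide is kept iff it ranks in the top fraction *q*
(default 10%) under all three scores simultaneously (ties broken
lexicographically).

**Biological filters** (`bio_filters`): a candidate gene passes if it is a
known substrate of the anchor phosphatase or of a phosphatase sharing
substrates with it (DEPOD-style table), or if it shares a KEGG/PID-style
pathway with the anchor's gene (GMT files).

**Pose criteria** (`pose_criteria`): a docked complex is accepted when,
after Kabsch superposition of its phosphatase Cα trace onto a reference
complex, (i) the pY phosphorus lies within 7 Å of the P-loop (residues
214–221) Cα centroid, (ii) the peptide's Cα(pY−2)→Cα(pY+2) vector is within
90° of the reference peptide's, and (iii) at least two of the three
signature hydrogen bonds form (Asp-48 carboxylate to backbone N of pY and of
pY+1; Arg-47 backbone N to backbone O of pY−2; heavy-atom distance ≤ 3.5 Å).

**Phosphopeptide masses** (`peptide_chem`): monoisotopic and average masses
of peptides with phospho (+79.966331 Da), N-acetyl (+42.010565) and C-amide
(−0.984016) modifications, and [M+H]⁺ / [M+Na]⁺ adduct m/z.

## Worked example

```bash
ptpscout simulate --out-dir data --seed 7          # synthetic proteomes + toy poses
ptpscout score --library-fasta data/query/proteins.fasta \
               --library-sites data/query/sites.tsv \
               --train-fasta  data/train/proteins.fasta \
               --train-sites  data/train/sites.tsv \
               --out-dir run --q 0.10 --seed 7
# 500 candidates (49 in consensus) -> run/candidates.tsv
```

The query proteome contains 500 annotated pY windows of which 50 carry the
planted substrate-like motif (acidic N-terminal stretch, cf. the known
substrate peptide EEEDIpYEVLPD); at *q* = 0.10 the consensus recovers 49
windows, essentially the planted class. Mass arithmetic for two synthesized
substrate peptides:

```bash
printf '1\tDPSDNpYAEPID\n6\tSTEPQpYQPGEN\n' > peps.tsv
ptpscout mass --peptides peps.tsv --out mass.tsv
```

| id | peptide | monoisotopic | calculated_mw | mz_H | mz_Na |
|----|---------------|-----------|------|-----------|-----------|
| 1 | DPSDNpYAEPID | 1355.49184 | 1355 | 1356.4991 | 1378.4811 |
| 6 | STEPQpYQPGEN | 1369.51874 | 1369 | 1370.526 | 1392.508 |

`calculated_mw` is the integer part of the monoisotopic mass of the
Ac-…-NH₂ phosphopeptide, the convention used in synthesis analytics; the
[M+Na]⁺ column is what a MALDI spectrum of the sodium adduct would show.
Pose evaluation of toy complexes:

```bash
ptpscout pose-eval --poses data/poses --reference data/poses/reference.pdb \
                   --out-dir poses_out
# 2/3 poses accepted -> poses_out
```

`pose_accept.pdb` (two of three H-bonds) is accepted; `pose_reject.pdb`
(one H-bond) is not.

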