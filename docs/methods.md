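# Methods

`glandscreen` re-implements, as a reusable library, the computational
analysis of a femoral-gland secretion proteome: cross-species annotation
transfer, gland-enrichment calling from iBAQ intensities, an in-silico
antimicrobial-peptide (AMP) screen, and broth-microdilution analysis.  This
note records the models, the parameters that matter, and the design choices
made where the procedure was genuinely open.

## Annotation transfer

For a non-model organism, protein identities are borrowed from alignment
hits against a panel of reference species.  Per query the lowest-E-value
hit in each organism is retained (ties: higher bit score, then subject id,
so results are order-independent).  The transferred label is the subject of
the globally best hit passing `evalue < 1e-20`; the panel of per-organism
bests is kept in the output so no information is collapsed away.  Several
queries may transfer to the same subject — paralog expansions are reported,
never merged.

Every query also receives a homology-confidence class from its best
E-value: class 1 below `1e-20`, class 2 between `1e-20` and `1e-5`
inclusive, class 3 above.  Both boundary values sit in the middle class, so
the three classes partition `[0, inf)` exactly.  A query is flagged as a
bacterial contaminant when its best contaminant-database hit passes the
transfer cutoff *and* beats its best cross-species hit.

Transfer efficiency is `100 * annotated / total`, rounded to one decimal,
half away from zero.

## Gland-enrichment calling

The gland is holocrine: whole cells disintegrate into the secretion, so
its protein list is dominated by shared cytosolic proteins.  Two selections
isolate the gland-specific signal from a protein x sample intensity matrix
in which 0/blank means "not detected":

* **unique set** — detected in at least one femoral-gland (FG) sample and
  in no other sample; computed on the unfiltered matrix because such
  proteins necessarily fail the valid-value filter.
* **enriched set** — after dropping serum (too few identifications to be
  informative) and requiring >= 1 FG value and >= 2 values elsewhere, each
  protein's detected intensities are log10-transformed and z-scored
  (population SD).  Missing cells are imputed at the row-minimum z minus a
  0.5 downshift — k-means needs complete vectors, and in MS data
  non-detection concentrates at the low-abundance end.  k-means
  (k-means++ initialisation, fixed seed, <= 300 iterations) partitions the
  z-profiles; the FG cluster is the one whose centroid is highest over the
  FG columns.  A principal-component analysis of the FG/SF (seminal-fluid)
  submatrix gives each protein a score on the first component, with the
  component's sign normalised so that FG-high proteins score positive; the
  enriched set is the part of the FG cluster whose score exceeds the 75th
  percentile of all scores.

Defaults and why: `k = 6` (about the number of sample classes; the FG
cluster is chosen by its centroid, so the calling is robust to k),
`loading_quantile = 0.75` (a "subset of the cluster" semantics without
inventing a sharper boundary), `downshift = 0.5` z-units, log base 10
(intensity data are log-normal in scale).  All four are configuration
values.

The combined set is the union of the two selections, ranked by mean
detected FG intensity (ties by protein id).  `fraction_abundance` reports
per-sample intensity shares (share = intensity / detected column total) for
the top-N proteins of each gel fraction.

## AMP screen

**Curation.** Labelled AMP/background sequences are restricted to 5–100
residues and de-redundified at < 90% pairwise identity.  Identity is
matches divided by the length of the shorter sequence under the best
ungapped offset alignment — cheap, deterministic, and in the spirit of
standard redundancy-removal tools; no alignment program is run.  The greedy
pass visits sequences longest-first (ties by sequence then id) and drops a
sequence when it is >= 90% identical to anything already kept; this equals
brute-force all-pairs filtering in the same visit order (tested against
that oracle).  The negative class must be supplied explicitly — the
package refuses to invent one.

**Features.** Chou's pseudo amino acid composition with the classic
three-property correlation (hydrophobicity, hydrophilicity, side-chain
mass, each standardised over the 20 residues): `theta_j` averages
`Theta(r_i, r_{i+j})` over the sequence for `j = 1..lambda`, and the
20+lambda vector is jointly normalised to sum to exactly 1 with
sequence-order weight `w`.  Defaults `lambda = 4` (windows may be as short
as 8 residues and lambda must stay below the length) and `w = 0.05` (the
classic default).  Auxiliary descriptors: net charge at pH 7 from a
per-residue Henderson–Hasselbalch model (EMBOSS pKa set, charged termini),
isoelectric point by bisection of the same model, GRAVY, Guruprasad
instability index (dipeptide weights from Biopython's table; agrees with
`ProteinAnalysis.instability_index`), aromaticity, and length.  A
length-batched vectorised path makes proteome-wide scans tractable and is
tested to agree exactly with the scalar reference path.

**Training.** Four SVM kernels (RBF, linear, polynomial, sigmoid) are
tuned by exhaustive grid search — cost in {0.1, 1, 10, 100}, RBF/sigmoid
gamma in {0.001, 0.01, 0.1, 1}, polynomial degree in {2, 3} — under
3-fold stratified cross-validation, with feature standardisation fit
inside each training fold.  The winner is the kernel with the highest CV
accuracy (ties: AUC, then a fixed kernel order).  Because a maximum over a
grid is optimistically biased, the reported accuracy and AUC of the winner
are re-estimated on a fresh CV split that played no part in the selection;
under label permutation the reported AUC then averages to chance.

**Scoring.** Every 8–15-residue window of every protein is scored (step 1,
duplicate sequences collapsed with all loci recorded).  Decision values are
mapped to `P(AMP | decision)` by isotonic regression on the held-out
decision values, interpolated linearly between knots, so the map is
monotone and raising the threshold can only shrink the candidate list.
Calibrating to the class probability rather than to the mixture rank
matters at scan time: an 8–15-mer can sit above essentially every
background training sequence yet only mid-range among the (much longer)
positives, and it should still score near 1.  Default acceptance
threshold: 0.8.

**Synthesis filter.**  The choice of peptides for synthesis is modelled by
two declared, configurable proxies (the original selection was by manual
inspection, so these rules are a reinterpretation, not a reconstruction):
soluble iff hydrophobic-residue fraction (`ACFILMVW`) < 0.45 and |net
charge| >= 0.5 (a strict "charge not zero" is vacuous under a continuous
charge model); stable iff instability index < 40 and no Asp-Pro bond and
at most one Met.  Under these defaults the printed reference peptide
KKLYISKGCMSKSLC passes the solubility rule but fails the instability rule
(index 49.0) — evidence that the original manual selection did not apply
the classic instability threshold.

## Microdilution analysis

The dilution series divides a stock repeatedly by the dilution factor
while the value stays at or above the floor, kept as exact rationals
(1000 -> 500 -> 250 -> 125 -> 62.5 -> 31.25 ug/ml for the reference
protocol).  Relative growth inhibition is
`100 * (1 - (mean(OD_test) - blank) / (mean(OD_ctrl) - blank))`, duplicates
averaged first, blank 0 when absent, clamped to [0, 100] with a log line
(per-replicate curves are also emitted).  The MIC is the lowest tested
concentration reaching a threshold inhibition — 90% by default, stated in
every report, since no operational MIC definition was published.  Dose
dependence is formalised as a positive Spearman correlation between
concentration and inhibition with a one-sided exact permutation p < 0.05
(exact enumeration up to 8 concentrations; constant curves report rho = 0,
p = 1).

## Synthetic data

The generator produces every input the pipeline consumes, with the
planted truth returned separately and never written into the data files.
What it emulates, and what it does not:

* **Proteome** — lengths from a normal (default mean 350, SD 150 residues)
  truncated at 30; residues i.i.d. from average Swiss-Prot frequencies.
  No homology, domains, or repeats.
* **Intensity matrix** — the sample panel has the gland secretion as seven
  FG-tagged gel-fraction columns plus seminal fluid, serum, erythrocytes
  and five tissues.  Log10 intensities are protein baseline (N(7, 1)) +
  a shared per-sample offset (SD 0.3 decades, protein-specific sensitivity
  around 1 — the protein-load/instrument variation that makes even
  housekeeping profiles co-vary) + i.i.d. cell noise (SD 0.25 decades).
  75% of proteins are tissue specialists, elevated ~1.2 decades in one or
  two non-gland sample groups: the co-expression structure that makes a
  tissue panel clusterable at all.  Planted gland proteins (default 40)
  get +log10(fold) in every FG column and half the log-effect in seminal
  fluid; every protein enters the specialist lottery, so at fold = 1 the
  planted subset is exchangeable with the background and recovery must
  fail.  Dropout concentrates sharply at the low-intensity end
  (`p = min(1, c (1-u)^8)` on the global intensity rank `u`, `c` set in
  closed form so the expected missing fraction equals `missing_rate`),
  matching detection-limit behaviour; this is also what justifies the
  low-value imputation upstream.  The generator does not model
  protein-group ambiguity, shared peptides, or batch effects.
* **Hit tables** — a configurable fraction of proteins receives a
  qualifying best hit (log10 E-value uniform on [-250, -21]) in one of 11
  reference organisms plus weaker hits spread over the two lower-confidence
  classes; the rest get weak hits or none.  E-values are planted, not
  computed from sequences.
* **AMP corpora** — positives build in cationicity (each position is K/R
  with probability `amp_charge_bias`) and period-2 hydropathy alternation
  (`amp_hydropathy_bias`); negatives are background composition.
  Amphipathy as period-2 alternation (rather than helical-wheel moments)
  is enough to create classifier-learnable structure at desk scale.
  `plant_amp_motifs` overwrites such segments into background proteins at
  known loci for recovery experiments.
* **Plates** — OD600 = `1 - Emax * c^h / (EC50^h + c^h)` plus Gaussian
  noise; control wells read 1.0 before noise.  A Hill family was chosen
  because only endpoint inhibition is analysed and its two parameters are
  interpretable; no growth kinetics are modelled.

Every generator is a pure function of (parameters, seed): identical seeds
give identical bytes.

Passing tests on these data show that the pipeline recovers structure *of
the kind the analysis assumes* at desk scale; they do not certify
performance on real MS data, where missingness is only approximately
intensity-driven, intensities are not log-normal, and homology structure
is real.

## Problem sizes

The default end-to-end run uses 60 proteins (mean length 120), 120+120
training peptides and four plates, completing in about 15 s; enrichment
recovery experiments use 500 proteins with 40 planted; classifier checks
use 200 training sequences.  These sizes keep every planted signal
recoverable while the whole suite stays quick to iterate on.

## Numerical choices

* z-scores use the population SD (ddof 0); zero-variance rows are a hard
  error naming the proteins.
* PC1 is computed by SVD; its sign is fixed by the FG coordinate of the
  component (FG-high positive), so "high loading" is orientation-free.
* Quantile thresholds compare strictly (`>`), making `quantile = 0`
  degenerate to the whole cluster and `quantile = 1` to at most one
  protein.
* E-value ties in best-hit selection break by bit score then subject id;
  kernel ties break by AUC then a fixed kernel order — every pipeline
  output is reproducible byte-for-byte under a fixed seed.
* Serialised models store scaler constants, support vectors, dual
  coefficients and the calibration map; a stored reference decision value
  disambiguates the decision sign, which the underlying SVM library does
  not preserve across reconstruction.
* The exact permutation test enumerates all n! inhibition orderings for
  n <= 8 concentrations and falls back to the asymptotic p beyond that.

## Known limitations

* Identity filtering is ungapped; gapped near-duplicates above 90%
  gapped-identity can survive curation.
* The solubility/stability rules are proxies; they reproduce a documented
  decision procedure, not the original manual one.
* PCA-loading selection uses only the first component of the FG/SF
  submatrix; information in the tissue columns reaches the enriched set
  only through the clustering step.
* MaxQuant-style protein groups are treated as one id per row; group
  members are not expanded.
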