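# Methods

This note documents the models, conventions and parameter choices behind
`isgarden`, in the order the pipeline runs.

## Coordinates and conventions

All positions are 1-based with closed intervals.  Insertion positions are
relative to the transcription start site: +1 is the first transcribed
nucleotide, the 5′-UTR spans [1, 88] and the reporter CDS (+89, +1510] in
the default geometry (88-nt leader + 1422-nt CDS).  The geometry is
configurable (`utr_len`, `cds_len`) because some labelling conventions
count from the start codon instead.  Every table written by the pipeline
carries a comment line stating the convention.

## Synonymous GC recoding

`recode_to_gc` is a deterministic greedy pass: at each step it applies the
synonymous codon swap that moves GC content furthest toward the target,
breaking ties by leftmost codon and then lexicographic codon order, and
stops when no swap reduces the remaining distance.  Translation (NCBI
table 11) is preserved exactly; a target outside the synonymously
reachable range returns the best achievable sequence flagged
`unreachable`.  Greedy rather than integer-programming optimisation was
chosen for auditability and reproducibility; on small instances
(exhaustively enumerated in tests, ≤ 8 codons) the greedy maximum equals
the true optimum, because per-codon GC contributions are independent.

## Motif scanning and target sites

Degenerate motifs use IUPAC codes matched by set membership; overlapping
occurrences are counted; the default is forward-strand only, with a
`both` policy that also scans the reverse-complement motif and reports
deduplicated forward-strand coordinates.  Both policies are exposed
because published site counts rarely state which was used.  Motif strings
are input data, not hard-coded: some ISs are best described by a short TSD
motif (WNA, WHW, TA), others by longer site strings.

## TSD detection

Given a reference and a mutant allele differing by one contiguous
insertion, the breakpoint is placed at the end of the longest common
prefix *p*; the inserted segment is `mutant[p+1 … p+L]` (L = length
difference) and the TSD is the longest k ≤ `max_tsd` for which the k
nucleotides ending at *p* equal the tail of the inserted segment (capped
at L − 1 so the element itself is never empty).  When flanking homology
makes the breakpoint ambiguous the duplication is reported as far left as
the common prefix allows; the recovered (position, element, TSD) always
regenerates the observed mutant exactly (property-tested), though the
reported position can shift from the generative one in degenerate flanks.

## Mutation frequency

A selective plate showing A colonies at dilution 10⁻ᵃ and a control plate
showing B colonies at dilution 10⁻ᵇ estimate the mutant fraction as
(A/B)·10^(a−b): each count is scaled back to undiluted-culture
concentration before the ratio.  Note the convention: 10⁻ᵃ multiplies the
plated aliquot, so *less* dilution of the selective plate (a < b) pushes
the estimate *down*.  The common shorthand "(A·10⁻ᵃ)/(B·10⁻ᵇ)" read
literally would do the opposite and produce frequencies above 1 for rare
mutants; the concentration-ratio form is the physically consistent one
and reproduces the expected 10⁻⁶–10⁻⁵ magnitudes.

## Hotspots and enrichment

Clones are tallied per distinct position; positions above Q3 + 1.5·IQR of
the tally distribution (linear-interpolation quartiles) are flagged, which
requires at least four distinct positions.  Fisher exact enrichment of an
IS in a garden uses a 2×2 of {this IS vs others} × {this garden vs other
gardens in scope}, with scope either the focal garden's replicon or all
gardens; Benjamini–Hochberg q-values accompany raw p-values across the
IS × garden scan.  All tallies weight events by their independent-clone
counts.

## OMI / WitOMI

The environment table (gardens × variables) is standardized column-wise
with uniform garden weights and the 1/n variance divisor, making the grand
centroid G the origin; constant columns are dropped with a warning.  The
garden-space gradients are summarized by PCA of this standardized table
(`environment_pca`).

For each IS the abundance-profile weights give a niche centroid u, and
the inertia decomposition I = OMI + Tol + Rtol holds to 1e−10 relative
(tested): OMI = ‖u‖² is marginality, Tol the abundance-weighted variance
of garden coordinates projected on the unit marginality vector, Rtol the
remainder.  When OMI = 0 the marginality direction is undefined and
Tol := 0, Rtol := I.  The niche ordination axes are eigenvectors of the
abundance-weighted centroid cross-product Σᵢ πᵢ uᵢuᵢᵀ, so the eigenvalue
sum equals the community-mean marginality; axis signs are fixed by making
the largest loading positive.

Subsets are delineated by agglomerative Ward (minimum-variance) linkage on
Euclidean distances between standardized garden rows, cut at k ∈ {2, 3},
with labels renumbered by first appearance for determinism.  Historical
implementations differ in whether squared distances are pre-applied
("ward.D" vs "ward.D2"); the modern minimum-variance criterion is used
here, and for the separated-cluster structure of garden tables the cut
equals the exhaustive minimum-variance partition (verified by brute force
on instances ≤ 7 sites).  On unstructured data the greedy cut can be
suboptimal — delineation results on weakly structured tables should be
read with that in mind.

WitOMI restricts an IS's counts to a subset's gardens, renormalizes, and
scores the sub-centroid against the global origin (WitOMI_G) and the
subset origin (WitOMI_GK).  An IS absent from a subset is reported absent,
not zero.  The count-share-weighted sub-centroids rebuild the global
centroid exactly (Σ_K f_K u_K = u, tested to 1e−10).

### Permutation tests

All tests are Monte-Carlo: p = (1 + #{null ≥ observed})/(n_perm + 1), one
seeded generator per run, permutations drawn row-by-row in table order so
results are bit-reproducible from (seed, n_perm).  The null for per-IS
marginality permutes that IS's counts across gardens (within a subset's
gardens for WitOMI); for subset distinctness it permutes garden→subset
labels (statistic: the subset's between-subset inertia contribution
n_k‖g_k − G‖²); for per-variable contribution it permutes labels with the
variable's between-subset variance share as statistic — a labelled
stand-in, since no canonical statistic exists for "variable significance"
in a delineation.  An empirical p cannot fall below 1/(n_perm + 1), and
with nine gardens the label-permutation null is additionally coarse (84
distinct 3/6 labelings); published astronomically small p-values for such
tests come from analytic tail approximations, so each result also carries
a clearly-labelled Gaussian tail approximation (`p_normal_approx`) from
the null mean and SD.  Default n_perm = 1000 (999 in the power and
calibration studies).

## The generative model

`simulate` produces every input the analysis consumes.  Nine gardens are
built from a random 1422-nt CDS pinned by synonymous recoding at GC
38.8/54.6/61.6% (the low/medium/high reporter variants), placed on three
replicons with GC 59/62/62.6%.  Enzyme activity is modelled per strain as
a variant base (1.0/1.6/2.2 arbitrary units; the high-GC recode sits
closest to host codon usage and is assigned the highest expression) times
a replicon factor (pA 0.85, pB 1.0, Ch 1.05) times lognormal measurement
jitter (σ = 0.05).  The default IS community has ten members named by
family, with replicon-biased copy numbers (the dominant IS5-family element
0/1/7 in Ch/pB/pA) and family-appropriate target motifs.

Insertion events follow λᵢ₉ = baselineᵢ·exp(βᵢ·z₉)·sitesᵢ₉^γᵢ over the
standardized environment; counts are multinomial over (IS, garden) cells
given a total event count (or per-cell Poisson), positions are drawn among
that garden's motif sites with optional Dirichlet hotspot weighting, and
each event carries the duplicated target sequence.  The log-linear kernel
is this package's modelling assumption: it nests the indifference null
(β = 0, γ = 0) and yields tunable marginality.  Baseline rates are
order-of-magnitude choices for a realistic fixture, not estimates of any
real transposition rates.  Plating counts are Poisson in both plates given
culture size, true mutant fraction, dilutions and plated volume.

What the simulations do *not* emulate: selection dynamics during growth,
silencer (MucR/H-NS) mechanism — only a rate-scaling toggle is possible by
adjusting baselines — sequencing errors, or non-independence of clones
within a culture.  Passing tests therefore demonstrate correctness and
calibration of the statistics under the stated model, not the biology of
any particular strain.

## Bundled example data

`data/synthetic_catalog.tsv` is a synthetic 142-clone catalog constructed
to mirror the structure of a real reporter-trap screen: 34 5′-UTR and 108
CDS clones, a dominant IS5-family element with 65.7% of CDS events and
positional hotspots, an IS3-family element with flexible targeting that
concentrates in the high-GC pA garden, and minor community members.  It is
a stand-in, not measured data; analyses of it illustrate the pipeline.

## Problem sizes and numerical choices

The calibration study uses 500 simulated indifferent ISs (~60 events each)
with 999 permutations; the recovery study 200 replicates of an 80-event IS
concentrating ~90% of its events in the three low-GC gardens; the plating
study 1000 replicates at a true fraction of 10⁻⁵.  Exceedance comparisons
use a 1e−12 absolute slack so exact ties count as exceedances.
Eigenvalues are clipped at zero before computing percentage shares.
Fisher tests on zero-margin tables return p = 1 with a warning rather than
failing.

## Known limitations

* The per-axis split of the garden-space PCA depends on the balance
  between reporter-linked and replicon-linked variable blocks; with the
  synthetic variable set the two blocks are of comparable size, so the
  first two axes (together ~93%) split near-evenly rather than strongly
  favouring axis 1 as a differently weighted variable set would.
* Greedy recoding can in principle miss a globally optimal recode on
  interacting targets; verified exact on small instances, and adequate for
  GC targets, which decompose per codon.
* TSD calling assumes clean single-insertion alleles, not raw reads.
* Empirical permutation p-values are floored at 1/(n_perm + 1); use the
  labelled Gaussian approximation for tail comparisons, with caution.
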