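# Methods

`polyphage` packages two computational procedures used to study how
co-residing prophages (polylysogeny) are induced: a sequence arm that mines
and classifies the regulatory loci of linear plasmid-like phages, and an
imaging arm that quantifies, cell by cell, which prophage's lytic genes are
being expressed in two-colour smRNA-FISH stacks. This note records the models,
the defaults, and the choices made where the procedure left room for them.

## Locus mining

Linear plasmid-like phages carry a protelomerase (*telN*) and a replication
initiator (*repA*); the DNA between a convergent telN/repA pair is where the
lysis-control module (cI repressor, and in some phages a transcription-factor/
small-ORF pair) resides. The miner operates on 1-based, inclusive coordinates
throughout.

* **Convergence.** A pair qualifies when the genes sit on opposite strands
  with their 3′ ends facing: the `+` strand gene upstream of the `−` strand
  gene. Tandem and divergent arrangements never qualify.
* **Separation.** "Within 10 kb" is measured as the gap between the facing
  gene ends, `downstream.start − upstream.end − 1`, floored at 0 for
  overlapping genes, with an inclusive cap (gap ≤ 10 000 bp by default). The
  gap-wise convention is chosen because the object of interest is the
  intervening DNA itself: `extract_intervening` returns exactly `gap_bp`
  forward-strand nucleotides.
* **Hit filtering.** All identity/coverage/e-value comparisons are inclusive
  (≥, ≥, ≤). Query coverage of a 12-column BLAST tabular file is derived
  from the aligned query span and requires query lengths; a 13th column is
  read as a precomputed coverage.
* **Context classification** of a transcription-factor gene uses fixed
  precedence: `repA_telN` (anchor overlapping the outer span of a convergent
  pair padded by 1 kb) → `parB_proximal` (a parB gene within 5 kb of the
  anchor boundaries) → `terminase_portal_proximal` (terminase or portal
  within 10 kb) → `heterogeneous`. The precedence resolves anchors that
  satisfy several rules; labels are independent of feature order.
* **parB-anchored search.** A contig qualifies when it has a capsid hit at
  ≥ 25 % identity over ≥ 70 % of the capsid query, a parB hit covering
  ≥ 90 % of the parB query (our operational definition of "full-length",
  which has no standard numeric definition), and a predicted TF within 10 kb
  of the parB boundaries.

## Clustering and repressor calls

`greedy_cluster` reproduces cd-hit-est-style semantics (`-c`/`-aS`): sequences
ranked by decreasing length (ties by id), the longest unassigned sequence
seeding a cluster, later sequences joining a seed when identity ≥ the
threshold over ≥ the coverage fraction of the shorter sequence. Assignment
defaults to the best-matching (highest-identity) seed, with a first-match
option; the choice is recorded in the API. There is no k-mer prefilter —
every comparison is a full global alignment (Biopython `PairwiseAligner`,
match +1, mismatch 0, gap open −5, extend −0.5, all config-exposed), trading
speed for exactness at the scales this package targets (tens to hundreds of
locus-sized sequences).

Percent identity is reported with the **shorter sequence's length** as the
denominator. This is the clustering tool's convention; note that published
pairwise-identity figures sometimes use the full alignment length instead,
which gives smaller values when gaps are present.

`dereplicate_exact` implements the identity-1.0/coverage-1.0 limit with
literal substring semantics: exact duplicates and exact substrings of longer
retained sequences are removed, nothing else ever is.

Autoproteolytic-repressor calling has two modes. The primary mode ingests a
conserved-domain feature table and calls a protein autoproteolytic iff a
catalytic-site feature is annotated for it. The heuristic fallback (clearly
lower confidence) scans the sequence for an S24-peptidase-like geometry: an
Ala-Gly or Cys-Gly cleavage motif at least 40 residues in, a catalytic serine
20–60 residues downstream, and a lysine 30–60 residues after the serine —
windows that bracket the canonical lambda cI spacings (cleavage Ala111/Gly112,
Ser149, Lys192). The synthetic repressor generator plants or destroys exactly
this motif and samples filler residues from an alphabet without Gly/Ser/Lys so
the motif's presence is unambiguous; those sequences are synthetic constructs,
not natural repressors.

## smFISH spot quantification

The imaging chain is: Gaussian denoise → negative-control threshold → local
maxima → 3D (multi-)Gaussian fit → integrated background-subtracted
intensity.

* **Denoising** convolves with a normalized 3D Gaussian (reflective
  boundaries; total intensity conserved in the interior). The kernel width
  defaults to (1, 1, `voxel_xy/z_step`) voxels — isotropic in physical units —
  and is config-exposed. Because convolution preserves the integral of a
  spot, fitting the denoised stack still recovers the true integrated
  intensity; only the apparent widths grow.
* **Threshold.** The default statistic is the maximum intensity among the
  local maxima of the (identically denoised) negative control; a quantile of
  those maxima is the alternative. Detection uses a strict `>` comparison, so
  by construction, running detection on the negative control itself yields
  zero spots — the pipeline's false-positive guarantee.
* **Maxima** are voxels strictly greater than all 26-connected neighbours;
  a constant plateau that is a regional maximum contributes its lowest
  (z, y, x) voxel. Candidates closer than 2 voxels merge, keeping the
  brighter.
* **Fitting.** Each candidate window (default ±4 px laterally, ±3 planes
  axially) is fitted with `B + A·exp(−Σ dᵢ²/2σᵢ²)` by bounded trust-region
  least squares with an analytic Jacobian, initialized at A = peak − window
  minimum, B = window minimum, σ = (1.4, 1.4, 1.2) voxels (bounds 0.3–3).
  The reported intensity is the analytic volume `A·(2π)^{3/2}·σx·σy·σz`
  rather than a discrete masked sum; the two agree on noiseless spots and the
  analytic form is insensitive to window clipping. Non-converged fits are
  flagged and excluded downstream, as are fits whose width pins at the upper
  bound: a "spot" much wider than ~2× the nominal PSF is extended background
  structure (e.g. the elevated cell interior) rather than a diffraction-
  limited transcript, and keeping such runaway fits would let a single false
  candidate dominate a cell's summed intensity.
* **Multi-spot fits.** Candidates whose windows overlap (optionally, whose
  centres are within a configured radius) are fitted jointly as a sum of
  Gaussians over one shared background. Groups larger than 5 are flagged
  unresolved and excluded — mirroring the practice of excluding cell groups
  that cannot be resolved. A single-candidate group reduces exactly to the
  single fit.

## Per-cell quantification and quadrants

Spots are assigned to cells through the 2D label mask (segmentation is done
on z-projections; z is ignored). Per cell and channel, spot intensities are
summed and totals ≤ 1 — including zero-spot cells — are replaced by exactly 1
(the pseudovalue), so uninduced cells sit at 1 on log axes. Quadrant
boundaries default to the maximum total of the uninduced population per
channel (quantile optional; the statistic and n are always recorded), and a
cell is called induced in a channel only when its total is strictly greater
than the boundary. The four classes (`none`, `a_only`, `b_only`, `both`)
partition the cells and their fractions sum to 1.

## qPCR, RLU and screening formulas

Fold change is `2^(−ΔΔCt)` with ΔΔCt referenced to a housekeeping gene
(e.g. *rpoB*); relative viral load is the no-reference variant
`2^(Ct_uninduced − Ct_induced)`; the induction ratio is the quotient of two
loads (so a 140-fold increase against a 0.2-fold change is a 700-fold ratio).
Amplification efficiency is fixed at 2 — the comparative-CT assumption — and
technical replicates are averaged on the Ct scale before exponentiation
(averaging folds instead would bias the estimate upward under replicate
noise). RLU is bioluminescence divided by OD600. A screening compound is a
specific hit when it triggers the target-phage arm (reporter fold strictly
above twofold, or growth decline) without triggering the lambda-control arm.

## Synthetic data: what it emulates and what it does not

The genome simulator plants labelled telN/repA/parB/capsid/TF intervals on a
random backbone at a chosen GC; `random_pair_plans` draws convergent, tandem
and divergent pairs with gaps 0–15 kb, spanning both sides of the 10 kb cap.
It tests coordinate logic, not gene calling: planted features are intervals
with labels, as the miner ingests annotation output rather than predicting
genes.

The scene simulator renders elliptical cells on a jittered grid (no overlap
by construction), draws a per-cell induction class from the designed
fractions, gives each induced channel `1 + Poisson(mean − 1)` spots
(zero-truncated, so a designed induced cell always expresses; default mean
3), renders each spot as an anisotropic 3D Gaussian (default
σ = (1.4, 1.4, 1.2) voxels, amplitude ≈ N(150, 20) truncated at 50 over a
cellular background of 20 counts), and acquires with Poisson shot noise plus
Gaussian read noise (sd 2) — peak SNR ≈ 10. The negative control is the same
cell field rendered with zero spots, an idealization of the biological
negative controls used at the bench. Acquisition presets `vibrio` (1 µm
z-steps) and `aeromonas` (0.4 µm) match the two imaging configurations.
Deliberately absent: realistic PSFs, photobleaching, autofluorescence
texture, segmentation errors, and cell-to-cell expression gradients. Passing
the end-to-end tests therefore shows the analysis chain is correct and
well-calibrated under its stated noise model — not that it is robust to
every artefact of real micrographs.

The Ct-table generator inverts the comparative-CT model: designed folds are
written into target Ct shifts with optional replicate noise, so the analysis
formulas recover the design exactly at zero noise.

## Problem sizes and determinism

The shipped tests run the end-to-end imaging check on three 500-cell scenes
(600×600×10 voxels) — a mixed 0.40/0.30/0.10/0.20 design, an A-module-only
design, and an uninduced boundary-reference scene — and verify recovered
fractions within three binomial standard errors of the design and module
exclusivity at ≤ 2 % off-channel calls. Spot-fit accuracy is measured on 200
planted spots (median intensity error ≤ 5 %, lateral localization ≤ 0.5
voxel at SNR ≥ 5; noiseless recovery to 0.1 %). Clustering is verified
against an independent brute-force dynamic-programming oracle on 50
sequences. Every stochastic component draws from a `numpy` Generator seeded
explicitly; identical seeds give identical artifacts.

## Known limitations

* The heuristic repressor caller is a motif screen, not a profile-HMM or
  structural prediction; on natural proteins it is advisory only.
* Greedy clustering is O(n²) alignments and is not meant for more than a few
  thousand sequences.
* The quadrant boundaries depend on the chosen uninduced statistic; with few
  uninduced cells the max statistic is noisy, and the quantile option should
  be preferred.
* Spot assignment uses spot centres only; transcripts in overlapping cell
  footprints are resolved by the mask, not by 3D reasoning.
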