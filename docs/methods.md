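# Methods

## Overview

`chromoclust` detects prevalent morphologies ("clusters") in large ensembles
of single-cell 3D chromosome structures, as produced by population-based
genome modelling at fixed genomic resolution (typically 200-kb bins, bead
radius R_bead = 118 nm, spherical or ellipsoidal nuclei).  The method has
four stages:

1. **Representation.** Each chromosome copy of each cell becomes a pairwise
   bead distance matrix.  The embedding input uses surface-to-surface
   distances, `d_ij = ||x_i − x_j|| − 2 R_bead` (0 on the diagonal), divided
   by the matrix maximum so all entries lie in [0, 1]; unrestrained
   centromere/telomere ("cen") beads are removed first.  Feature calculations
   use center-to-center distances with min–max normalization.  Matrices are
   resized by bilinear interpolation to the nearest multiple of 50
   (= 5·5·2, the product of the pooling windows), ties rounding down.
2. **Two-step dimension reduction.** A convolutional autoencoder (encoder:
   three conv layers of 16/8/4 filters, 10×10 kernels, stride 1, same
   padding, ReLU, with max-pool windows 5, 5, 2; decoder mirrored with
   nearest-neighbour upsampling and a final 1-filter sigmoid conv) is trained
   for 15 epochs with Adadelta on the summed-square reconstruction loss.
   The latent map — (side/50)² × 4 values, 625× smaller than the input — is
   flattened (spatial row-major, channels last), z-scored per dimension over
   the set, and embedded in 2D by t-SNE (perplexity 200, learning rate 1000
   at full scale).
3. **Density clustering.** After 3-sigma outlier removal on the row sums of
   the pairwise distance matrix of the 2D points, a Gaussian KDE (Scott's
   rule) is evaluated on a square grid spanning the data.  Local maxima are
   cells equal to their 5×5 maximum filter (nonzero); for each peak the
   iso-density contour is raised through 100 levels from 0 to the density
   maximum until it encloses only that peak, realized as superlevel-set
   connected components with holes filled.  Points inside the final region
   form the peak's cluster; clusters below the minimum size (100 at full
   scale) are discarded.  Quality is reported as the mean and per-cluster
   silhouette coefficient of the clustered points.
4. **Profiling and classification.** Per cluster: contact-frequency matrices
   (contact iff center distance ≤ 3 R_bead, inclusive), average normalized
   distance matrices, insulation scores (contact and distance variants),
   territory-domain boundaries (coarse 40-Mb / fine 6-Mb window two-pass
   calling), P(s) curves, local radius of gyration (1-Mb window), radial
   position and variability, A/B compartment eigenvectors, speckle-derived
   tracks (SpD, SON TSA-seq, SAF), proximity maps and IPP — each compared
   against the ensemble of all clustered structures by log2 ratio tracks.
   External single-cell data are classified against the clusters: sparse
   single-cell Hi-C maps after box-convolution (w = 5), random walk with
   restart (p = 0.5, Frobenius tolerance 1e−6) and per-row 75th-percentile
   binarization, scored against superiority (d ≥ 5) / inferiority (d ≤ −1)
   masks with an assignment margin of 0.01; chromatin-tracing structures by
   the Pearson correlation of min–max-normalized upper-triangle distance
   vectors against cluster averages downsampled to the imaged loci, margin
   0.05.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| R_bead | 118 | nm | bead radius; enters surface distances, contact (3R), speckle edges (4R) |
| contact threshold | 3·R_bead, inclusive | nm | binary contact definition |
| insulation binarization | 0.45 | – | distance-variant threshold (stated range 0.4–0.5) |
| boundary windows | 40 Mb / 6 Mb | bp | coarse candidate / fine refinement windows |
| KDE grid | 1000 (full), 500 (desk) | cells/axis | density resolution |
| min cluster size | 100 (full), 30 (desk) | structures | discard small density basins |
| t-SNE perplexity | 200 (full); min(200, max(30, n/10)) otherwise | – | neighbourhood scale |
| autoencoder batch | 200 (full); ~1% of n (8–200) otherwise | structures | keeps ~100 optimizer updates/epoch |
| speckle edge / size | 4·R_bead, >3 nodes | nm, beads | A1 interaction network and subgraph filter |
| TSA-seq decay k | 4 | per µm | exponential distance decay |
| SAF threshold | 1000 (models), 500 (tracing) | nm | association distance |
| R_soft | 2000 | nm | proximity-map radius |
| RWR restart p | 0.5 | – | imputation restart probability |

Desk-scale values exist because density-based clustering is
sample-size-dependent: perplexity must stay below the per-cluster point
count, and the batch size must leave enough optimizer updates in 15 epochs.
Both rules reduce to the printed constants at the full 20,000-structure
scale.

## Numerical choices

* Surface distances of overlapping beads are clipped to 0 before
  max-normalization, keeping inputs in [0, 1].
* The resize preserves corner values exactly (sampling grid from index 0 to
  side−1); ties in "nearest multiple of 50" round down.
* The convolutional layers run as FFT products with keras-style same padding
  (4 left, 5 right for the 10×10 kernel); gradients are exact adjoints and
  are tested against direct `scipy.signal` convolutions.  Max-pool routes
  gradients to the argmax; upsampling backward sums its window.  Adadelta
  uses rho = 0.95, eps = 1e−6, no learning rate.  Weights are Glorot-uniform
  from the run seed; the training set is shuffled once with the same seed,
  so the whole embedding is deterministic given (seed, spec, input order).
* With a narrow bottleneck (4 latent channels at small matrix sides) training
  can collapse onto the mean predictor — all bottleneck ReLU channels dead,
  loss flat near its starting value.  The trainer detects this from the
  training curve alone (final epoch loss above half the first epoch's) and
  restarts from a derived seed, keeping the best of up to 4 attempts by final
  reconstruction loss.
* Latent z-scoring maps zero-variance dimensions to 0.
* Peak detection treats cells below 1e−12 × max as zero (far-field KDE
  underflow ripple would otherwise create spurious peaks) and keeps only the
  lexicographically smallest cell of an equal-valued plateau.
* Degenerate (collinear) KDE inputs are jittered by 1e−9 × span, seeded.
* The watershed region of a peak is its superlevel-set connected component
  (holes filled) at the lowest of the 100 levels isolating that peak — the
  same region an explicit iso-contour polygon would bound, but robust to
  contours cut by the grid edge.
* δRAD with zero per-bin standard deviation, log ratios with nonpositive
  numerator or denominator, and TSA values at zero signal are NaN, never
  ±inf.
* Dissimilarity sampling: 200 structures per cluster without replacement,
  seeded; Wasserstein intra-cluster values use the half-split convention
  (sampled half vs reversed complement).
* The sci-Hi-C convolution filter is a box of ones with zero padding; the
  RWR convergence norm is Frobenius; row binarization keeps entries strictly
  above the row's 75th percentile.
* Markov clustering (speckles) is implemented natively: expansion 2,
  inflation 2.0, pruning 1e−5, clusters read off the converged flow's
  connected support.
* TSA-seq, SpD and SAF distances are bead-surface-to-speckle-center, in µm
  for the exponential decay (k = 4 per µm).

## Synthetic data: what it emulates and what it does not

The generators plant known structure so every stage has ground truth:

* **Reference conformations** are confined random walks whose planted
  territory domains are collapsed around displaced centers; clusters differ
  in boundary positions *and* qualitatively (territory elongation and
  compaction vary across clusters), mirroring how real morphology clusters
  differ in compaction, fragmentation and shape — not merely in boundary
  placement.
* **Positive controls** re-embed the reference distance matrix by classical
  MDS (exact for Euclidean matrices) and add isotropic coordinate noise with
  displacement rms sigma × RG(reference), sigma in {0.1, 0.4, 0.8}; one
  dataset per noise level.  True labels are retained for purity checks.
* **Negative controls** are confined self-avoiding homopolymers (overlap
  rejected below 2 R_bead) with no planted structure.
* **Speckle genomes** place A1 beads in tight, well-separated blobs with
  recorded centers.
* **Single-cell Hi-C** thins planted cluster contact probabilities to a
  target per-cell depth (default 3879 contacts, the observed mean coverage
  of combinatorially indexed single-cell Hi-C).

What passing tests on these fixtures demonstrate: the pipeline separates
genuinely distinct conformational states under substantial coordinate noise,
recovers planted boundaries to ±1 bin, finds no structured clusters in
unstructured polymers, and classifies sparse external observations back to
their generating state.  What they do not demonstrate: performance on real
modelled populations, where cluster differences are subtler and occupancy
highly unbalanced; polymer physics realism (no excluded-volume dynamics, no
Hi-C-restraint structure); or sequencing artefacts of real sci-Hi-C.

## Problem sizes used in the shipped checks

The checks run on desk-scale simulations chosen as the package's own
defaults: positive controls with 4 references × 50 beads × 250–500
structures per reference (one run per noise level), negative controls with
400 homopolymers, subsampling with 6 references × 150 structures, and
single-cell Hi-C recovery with 3 references × 150 beads and ~200 sampled
cells at 3879 contacts each.  The printed full-scale constants (grid 1000,
minimum cluster size 100, batch 200, perplexity 200) are restored by
`--paper-scale`.

## Known limitations

* The autoencoder is a compact native implementation; it reproduces the
  published architecture and optimizer but not any particular framework's
  floating-point trajectory, so latents match published runs only in
  distribution, not bitwise.
* Classical MDS in the positive-control generator discards negative
  eigenvalues; for non-Euclidean (noisy) matrices the embedding is the usual
  least-squares approximation.
* Chromosome-level clustering is restricted to autosomes; homolog copies are
  clustered separately and only proximity-map/IPP features average homologs.
* Lamina-distance features are provided only as radial-position derivatives
  (1 − r) and flagged non-canonical.
* The boundary caller assumes chromosomes at least twice the coarse window;
  shorter fixtures must pass smaller windows explicitly.
* At the highest positive-control noise level (sigma = 0.8, displacement rms
  equal to 0.8 × the reference radius of gyration) a small fraction of
  sampled structures can genuinely resemble a different reference and join
  its density basin; exact label purity at that noise level is a knife-edge
  property of any finite sample, not a guarantee of the method.
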