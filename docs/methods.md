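# Methods

## Problem and overall approach

Cryo-EM reconstruction maps at ~4 Å resolution show secondary-structure
elements — α-helices as rods, β-sheets as slabs, RNA/DNA as wide ribbed
spirals — but assigning them by eye is slow and error-prone, especially for
complexes of unknown composition. This package trains a 3D convolutional
encoder–decoder to classify every voxel of a map into one of four classes
(helix, sheet, nucleotide, unassigned), using deposited atomic models as
ground truth, and applies it to whole maps by tiled inference.

The pipeline has five stages, each independently usable:

1. **Map I/O and normalization** (`map_io`). Maps are MRC2014 volumes; all
   density thresholds are expressed in multiples of the map σ, defined here
   as the standard deviation of the voxel values about their mean (the
   EM-community convention for "map r.m.s.d."; whether the original
   convention was about zero or the mean is not documented — for maps with
   near-zero mean the two coincide). Maps whose voxel size falls outside
   [1.0, 1.2] Å are resampled to 1.1 Å by trilinear interpolation. New grid
   dimensions are `round(old_dim·old_voxel/1.1)` with round-half-away-from-
   zero; samples outside the original grid take 0, the mean level after
   normalization. Anisotropic voxel sizes are rejected outright rather than
   resampled per axis.

2. **Residue labels** (`model_annotation`). Nucleotide residues are always
   class `nucleotide`. For amino acids, three sources are merged: author
   HELIX/SHEET records (which win conflicts, because deposited annotations
   are the ground truth being learned); a hydrogen-bond analysis in the
   Kabsch–Sander style with energy
   `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol and bond
   threshold E < −0.5, the amide H placed 1.0 Å from N along the preceding
   C=O direction; and a torsion-angle extension. Helices are runs i..i+3
   covered by two consecutive i→i+4 bonds (only α-helices; 3₁₀ and π
   patterns are not separately detected, since the network has a single
   helix class). Sheets are residues participating in at least one
   inter-strand bridge; the parallel and antiparallel Kabsch–Sander bond
   patterns are accepted identically and no ladder direction or topology is
   recorded. The extension iteratively absorbs unassigned residues adjacent
   to a helix (sheet) when their (φ, ψ) lies in the helix window
   φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°) (sheet window φ ∈ (−180°, −45°),
   ψ ∈ (90°, 180°] ∪ [−180°, −150°)). These windows are standard
   α/β Ramachandran regions, exposed as configuration constants; the exact
   windows of the original torsion extension are unpublished.

3. **Voxel ground truth** (`voxel_labeling`). For each labeled residue the
   mean interpolated density over its backbone atoms (N, CA, C, O for amino
   acids; P, O5′, C5′, C4′, C3′, O3′ for nucleotides — sugar ring atoms are
   included so sparse phosphate-only models still gate sensibly) decides:
   above 2σ, voxels with centers within 3 Å of any backbone atom get the
   residue's class; between 1σ and 2σ those voxels are excluded from the
   loss (plausible but unreliable ground truth); below 1σ the residue
   contributes nothing. Voxels farther than 5 Å from every model atom with
   density ≥ 1σ are excluded as unmodelled density. Everything else is
   unassigned and trainable. When two gated residues claim a voxel, the
   nearest backbone atom wins; exact ties fall back to the fixed priority
   nucleotide > helix > sheet, and an annotate-band residue beats a
   mask-band residue at equal distance. These tie rules are this package's
   own choices (the original resolution is not documented); they make the
   output fully deterministic. The fast implementation updates per-atom
   voxel boxes with the same floating-point expressions as the brute-force
   all-pairs scan, so the two agree voxel-for-voxel, which the test suite
   asserts exactly.

4. **Training data** (`training_data`). Annotated maps are tiled into
   non-overlapping 70³ segments (stride 70; partial edge blocks are
   zero-padded and the padding excluded from the loss). Non-overlapping
   tiling avoids any train/eval leakage through shared voxels. A segment is
   kept if it has ≥ 100 model atoms at ≥ 1σ, backbone mean density ≥ 3σ,
   and ≥ 5% of its volume annotated. Samples are 40³ crops augmented by one
   of the 24 proper cube rotations and a uniform corner offset in {0..30}³;
   the target is the center-aligned 20³ label block. Loss weights are 16
   for structural voxels, 1 for unassigned, 0 for excluded — the 16:1 ratio
   is a fixed constant derived from the ~95% unassigned-voxel fraction of
   annotated EM maps, not re-estimated per dataset. The evaluation split is
   by segment (5%, at least one segment).

5. **Network** (`network`). A U-Net-style encoder–decoder: per level two
   same-padded 3³ convolutions + ReLU then 2³ max-pooling; a two-convolution
   bottleneck; a decoder with nearest-neighbour upsampling and skip
   concatenations; a final 1³ convolution to 4 channels, center-cropped to
   20³, softmax per voxel. Defaults: 3 levels, 32 base channels (doubling
   per level), Adam at 1e-4 with a 30-step linear warmup and cosine decay
   to 10%, global gradient-norm clipping at 1.0, weighted softmax
   cross-entropy normalized by the total voxel weight. The activation is a
   leaky rectifier (slope 0.01): σ-normalized EM density is sparse with
   excursions of 10–25 σ, and with plain ReLU an early violent update can
   kill entire channels irrecoverably — observed as training runs pinned at
   the uniform-prediction loss ln 4 — whereas the small negative slope keeps
   dead units trainable. Depth, widths, optimizer and loss are this
   package's choices — the original architecture details beyond the
   40³→20³ contract and four softmax channels are unpublished — and all
   are exposed in `NetworkConfig`.
   The implementation (forward, backpropagation, Adam) is written directly
   on NumPy arrays with per-offset GEMM convolutions; training and
   inference are bit-reproducible for a fixed seed on one machine. Because
   only the central 20³ cube is ever read, the decoder computes just that
   region plus the convolution halos; this is algebraically identical to
   full-volume computation (asserted in tests) and roughly halves the cost.

## Inference and output maps

Whole-map prediction tiles the σ-normalized (and, if needed, rescaled) map
with non-overlapping 20³ output tiles, each predicted from its 40³ context
window (map edges padded with 0 = mean level). Every voxel belongs to
exactly one tile, so stitching cannot create seams by construction; whether
the original tool used overlapping windows with averaging is unknown, and
the exact-cover rule is the simplest deterministic alternative. If the map
was rescaled, probabilities are trilinearly resampled back to the input
grid and renormalized, so the outputs overlay the user's map without any
transformation. The four output MRC maps assign each voxel's full input
density to its most probable class (ties: lowest channel index) — the only
rule under which the four maps literally sum to the input map, which is
asserted bit-exactly in the tests.

## Evaluation

Per residue, the predicted class is the majority argmax class over voxels
within 3 Å of its backbone atoms (mirroring the annotation radius; the
original aggregation rule is not documented). The evaluation set is
residues with mean backbone density ≥ 1σ where truth or prediction is
structural; true negatives are excluded, so tp + fp + fn = 100%. A wrong
structural class counts as fp only. recall = 100·tp/(tp+fn),
precision = 100·tp/(tp+fp), F1 their harmonic mean; multi-map reports give
medians across maps. Note one consequence of shell-based aggregation: a
truth-unassigned residue bordering a helix inherits structural votes from
its neighbours' shells, so even evaluating the ground-truth label volume
against itself gives slightly less than 100% precision (recall stays
exactly 100%); the identity `prediction = truth` holds exactly at the
residue level, which is what the self-evaluation test checks.

## Synthetic phantoms

The phantom generator builds ideal geometry from internal coordinates:
α-helices (φ=−57°, ψ=−47°, ω=180°, standard bond lengths/angles, ~1.6 Å
rise per residue), antiparallel β-sheets (extended strands at φ=−135°,
ψ=135°, successive strands flipped and rigid-body refined so narrow-pair
N···O distances hit 2.9 Å, giving genuine Kabsch–Sander double-bond
bridges), and simplified A-form-like single-stranded oligonucleotide
backbones (32.7° twist, 2.81 Å rise, P–P ≈ 6 Å). Density is a sum of
unit-height isotropic Gaussians (default width 1.0 Å, matching feature
sizes at the ≤ 4 Å regime) plus white noise (default 0.1 of the atom peak
height), σ-normalized.

A standard phantom is a 70³ box at 1.1 Å/voxel holding several elements of
one kind at random non-clashing poses — 8 30-residue helices, 3 six-strand
14-residue sheets, or 9 18-residue nucleic chains. These inventories were
chosen once so that a phantom passes all three segment filters (in
particular the 5% annotated-volume gate) with margin; occasional phantoms
whose random placement fails a gate are skipped with a warning.

What phantoms do not emulate: experimental error structure, B-factor
variation, map sharpening and other post-processing, side chains, partial
occupancy, solvent. Passing the phantom training check therefore
demonstrates that the pipeline's plumbing and optimization work end to end
— not that the tiny network would perform on experimental reconstructions,
which is exactly why simulated maps are unsuitable as a substitute for
experimental training data at full scale.

## Scaled-down training check

Full-scale training (hundreds of curated EMDB maps, 40 000 steps × 100
segments) is out of scope here. The package's own standing check trains a
small configuration (2 levels, 8 base channels, ~29k parameters, Adam at
1e-3 with cosine decay, 600 steps with 4 segments per step) on ~50 phantom
segments and requires ≥ 0.90 voxel accuracy (non-excluded voxels, center
crops) on six held-out phantoms. Holding out whole phantoms rather than
segments makes the accuracy estimate independent of the training boxes.
These problem sizes are the package's chosen desk-scale defaults; the same
run is reproduced by `scripts/acceptance.py`.

## Numerical choices and degenerate inputs

- Trilinear interpolation everywhere (map values at atom positions,
  rescaling, probability resampling); out-of-grid samples are 0.
- Constant maps are rejected (σ undefined) by `compute_sigma` and
  `predict_map`.
- Chains shorter than 3 residues are never analysed for hydrogen bonds;
  chain-terminal donors without a preceding residue cannot place an amide H
  and form no bonds; proline never donates.
- Alternate locations resolve to the highest occupancy (ties: first
  occurrence).
- All argmax ties (partition, per-residue majority) resolve to the lowest
  channel index; all randomness flows from a single seeded
  `numpy.random.Generator`.
- The header RMS field of written MRC files is always recomputed from the
  data, never copied from stale metadata.

## Known limitations

- No separate classes for 3₁₀/π helices, β-turns, or polyproline-II
  helices; PP-II in particular is a known α-helix confounder.
- The NumPy network is single-device and CPU-oriented; it is suitable for
  desk-scale experiments, not for corpus-scale training.
- Nucleotide gating reuses the protein 2σ/1σ thresholds (the gating rule
  is described only once in the source material).
- The evaluation-set convention (true negatives excluded) is one reasonable
  reading; published tp/fp/fn percentages that do not sum to 100 suggest
  the original denominator differed, so absolute fp rates are not directly
  comparable.
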