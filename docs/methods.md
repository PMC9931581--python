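# Methods

This note records the models, conventions and design choices behind
eelkit, and what its synthetic benchmarks do and do not establish.

## Barcode scheme

Codewords are binary vectors over n = 16 readout rounds with constant
Hamming weight w = 6 and guaranteed minimum pairwise distance d = 4.
For d = 4 the construction is the checksum residue class: among all
C(16,6) = 8008 weight-6 words, keep those with s(x) = Σᵢ i·xᵢ ≡ r
(mod 16) (0-based positions) for the residue r with the largest class,
ties broken toward the smallest residue. Two distinct equal-weight words
differ in an even number of bits; a 2-bit difference (one bit moved from
position i to j) changes s by j−i ≢ 0, so same-class words are at
distance ≥ 4. By pigeonhole the class has ≥ ⌈8008/16⌉ = 501 words; the
actual largest class has 504. The construction is deterministic and
needs no seed. For other (even) distances a greedy lexicographic
accept/reject scan is used instead. An optional `size` argument keeps
the lexicographically first codewords, matching the 448 codes a single
color channel uses.

Decoding is nearest-neighbor with `max_correct = 1`: d = 4 corrects any
single bit error and detects double errors. A distance tie or a best
distance > 1 is a no-call, never an arbitrary pick — arbitrary picks
would silently inflate gene counts and bias the blank-based
false-positive rate, which is defined here as per-blank decoded count
over total decoded molecules (mean ± sd across blanks; the denominator
convention is recorded in the function's output).

Gene assignment is deterministic in input order. When co-expression
groups are supplied, the assigner minimizes the number of same-group
gene pairs sharing an "on" round (greedy insertion followed by seeded
pairwise-swap hill climbing); leftover codewords become blanks, ordered
lexicographically so the blank set is reproducible.

## Probe design

Binding regions are scored with the unified DNA/DNA nearest-neighbor
free-energy table at 37 °C (1 M NaCl): ΔG°₃₇ = both terminal initiation
penalties plus the stack sum. No symmetry correction term is applied and
no salt or temperature adjustment beyond the 37 °C table is made, since
the design thresholds are themselves specified at 37 °C. Probes bind
RNA; a DNA/RNA hybrid table of the same shape can be substituted through
the `table` argument, but none is shipped.

Secondary-structure screening takes the minimum ΔG over (a) all hairpin
stems of ≥ 3 contiguous pairs enclosing a loop of ≥ 3 nt and (b) all
ungapped antiparallel self-alignments with runs of ≥ 2 complementary
pairs (homodimers), each stem scored as a standalone duplex. Because
every added stack lowers ΔG by more than the worst-case change in
terminal initiation (0.05 kcal/mol), maximal runs attain the minimum,
which is what the implementation enumerates; tests verify equality with
an exhaustive enumeration oracle.

Filters: duplex ΔG°₃₇ ≤ −28 kcal/mol; G+C 40–60%; structure ΔG°₃₇ ≥
−9.0 kcal/mol (structures stronger than −9 are disallowed); specificity
by 12-mer seed-and-extend against the panel transcriptome — a probe
fails with ≥ 5 distinct off-target transcripts containing an ungapped
window of > 60% identity. The seed requirement means hits sharing no
exact 12-mer are invisible; this is a deliberate fast proxy for a full
alignment search and is not equivalent to BLAST.

Candidates are enumerated at every offset and length 26–32 (ordered by
start, then length ascending) and tiled greedily left to right with a
minimum 2 bp gap, capped at 28 probes; genes with < 10 surviving probes
are dropped and reported. Assembled oligos place the binding sequence 5′
of a single tail containing all six readout sequences in an order
randomized per probe (seeded), each readout preceded by a 2-nt spacer
cycling TT, AT, TA, AA — so the assembled length is binding + 6×22 =
binding + 132 nt. The spacer-before-every-tail convention is recorded in
the panel metadata.

## Synthetic scenes and acquisitions

Coordinates are microns, origin at the image top-left, y increasing
downward; pixel index = floor(coord/pixel_size); a pixel's center sits
at (index + 0.5)·pixel_size. Defaults: 0.18 μm/px (an 11 μm camera pixel
behind a 60× objective) and PSF σ = 1.2 px.

Scenes place non-overlapping disk cells uniformly (rejection sampling),
draw per-cell per-gene molecule counts as Poisson with the cell type's
rates, scatter molecules uniformly within the disk, and add ambient
molecules and fiducial beads as uniform Poisson processes. Lateral
diffusion displaces each molecule by N(0, σ²I), keeping the origin, so
the radial displacement is Rayleigh with median σ√(2 ln 2).

The readout simulator emits, per molecule, a spot in each "on" round
with probability 1 − p_dropout and a spurious spot in each "off" round
with probability p_gain. Gain spots are colocated with the molecule,
modeling probe cross-talk; uniformly scattered false spots are a
separate knob (ambient molecules). Spots carry N(0, σ_loc²) jitter and
pass through each round's similarity drift transform. Real instruments'
bit-error rates are not publicly quantified; the defaults here are free
parameters chosen to exercise the decoder, not estimates of hardware.

Rendering sums Gaussian kernels over a constant background with optional
Poisson shot noise and Gaussian read noise, emitting 16-bit images.

## Spot pipeline

Background removal is a difference of Gaussians (defaults 1 and 5 px),
clipped at zero. Detection thresholds at median + k·(robust sd), where
the robust sd is the larger of 1.4826·MAD and the 84.13th-percentile
excess over the median — the two agree on symmetric noise, but MAD
collapses on zero-clipped band-passed images where more than half the
pixels are exactly zero. Subpixel positions come from an
intensity-weighted centroid over the 3×3 peak window after subtracting
the window minimum; without that local background removal the centroid
is so attenuated that positions quantize to the pixel grid (~0.3 px
RMSE); with it the bench measures ~0.18 px at SNR ≳ 10.

SNR = (peak − annulus mean) / annulus sd over radii 3–9 px, excluding
annulus pixels that fall within 3 px of any other detected spot.

Registration estimates a similarity transform (scale, rotation,
translation) by iterating mutual nearest-neighbor matching against the
closed-form least-squares (Procrustes/Umeyama) fit. Initialization
aligns centroids and RMS radii; the match radius anneals geometrically
from 30% of the point-cloud RMS radius down to the final radius
(default 2 μm), iterating to stability at each level. This single code
path converges for sub-micron round-to-round drift, degree-scale
rotations and the ~1.5× scale change between objectives. Beads and RNA
spots are distinguished by an `is_bead` flag in simulation or a
brightness threshold on images (the real instrument separates them by
excitation channel, which collapses to one channel here).

## Decoding and cell assignment

Candidate molecules are connected components of a graph joining spots of
different rounds within a match radius (default 0.75 μm); a component's
word has bit r set iff it contains a round-r spot, and rounds with
several member spots keep only the spot nearest the component centroid.
Two molecules closer than the match radius merge into one candidate —
a documented limitation of point-based aggregation. Merged different-gene
candidates acquire words of weight ≥ 8, which are necessarily no-calls
(distance ≥ 2 to every codeword), so merging loses molecules but never
fabricates blank or gene calls in an error-free channel.

Mask expansion assigns each background pixel within the expansion
distance (default 8 μm) to its nearest seed pixel by Euclidean distance;
exact ties go to the smaller label id. It is implemented as one distance
transform per label restricted to the label's padded bounding box, which
makes the tie rule exact rather than dependent on scan order; original
labeled pixels are never reassigned and overlap cannot occur. Molecules
are assigned by the expanded label under their (inverse-transformed)
position; blanks are excluded from the cells × genes matrix but
reported, and assigned + unassigned + blank counts equal the decoded
total exactly.

## Spatial statistics

Hex binning uses a pointy-top axial lattice; `spacing_um` (default
100 μm) is the center-to-center distance, and molecules are assigned by
cube rounding, conserving counts exactly. Before reduction, hex counts
are scaled to the median hex total and log1p-transformed (recorded in
grid metadata); LDA runs on raw counts instead, as is usual for topic
models. Regionalization is Ward agglomeration constrained by the hex
adjacency graph, so regions are spatially connected; region colors
follow a 1D spectral embedding of region-mean expression so similar
regions receive similar hues. Gradient visualization trains a
100-tree random forest (fixed seed) on hex expression → region label and
mixes region colors by predicted probability; any probabilistic
classifier could be substituted.

The border field takes, per grid point, the molecules within a 200 μm
radius, splits them with 12 equally spaced lines through the point and
reports the maximum over angles of the Euclidean distance between the
two half-disks' per-gene count vectors, with the argmax line orientation
in [0, 180). The distance is taken between per-gene count vectors: a
scalar molecules-per-half total would be angle-insensitive for balanced
splits and could not localize expression borders. Strength is raw
(count-scaled) by design; near the window edge, clipped disks imbalance
the halves by area alone, so analyses should either restrict to grid
points ≥ one radius from the data bounding box (as the tests do) or
flag such points. Disks under a minimum occupancy (default 10) return
strength 0 flagged `low_support`.

Ripley's K uses K(r) = A·Σ_{i≠j} w_ij⁻¹·1(d_ij ≤ r)/n², with the
isotropic correction w_ij = the fraction of the circle of radius d_ij
around point i lying inside the rectangular window (exterior arcs
2·arccos(dᵉ/d) per crossed edge minus the corner overlaps
π/2 − arcsin(dᵉ/d) − arcsin(dᶠ/d)); `none` and `toroidal` variants are
available. Radii are restricted to < half the shorter window side so a
circle can cross at most two adjacent edges. L(r) = √(K/π), reported
with L(r) − r.

The diffusion profile clusters a marker gene's molecules with DBSCAN
(clusters = putative cells), pools molecule–centroid distances and
reports the radius containing 50% of molecules; for Gaussian scatter of
sd σ this median is σ√(2 ln 2). Optical crowding scatters n points
uniformly in a 10 × 10 μm² area and counts a point resolvable iff its
nearest neighbor is ≥ λ/(2·NA) away; in the sparse limit the expected
fraction approaches the Poisson void probability exp(−nπd²/A), which the
tests verify to 2%. Cross-section region linking joins region-mean
expression vectors by gene name and greedily matches region pairs by
Pearson correlation above a threshold (default 0.7).

## Benchmark conditions and their scope

The end-to-end bench simulates 200 cells of radius 20 μm in a
2 × 2 mm field with 20 genes whose per-cell rates are log-spaced from
0.02 to 1.0 (≈ 1,000–1,100 molecules per run, matching the sparse
per-gene-per-cell occupancies of large panels) at p_dropout = 0.05,
p_gain = 0, σ_loc = 0.05 μm, with per-round drift of scale 0.99–1.01,
rotation ≤ 2° and shift ≤ 5 μm over ~200 beads. At this density the
probability that two molecules fall within the 0.75 μm match radius is
under 1%, so measured recall isolates the bit-error model and can be
compared to the binomial prediction (1−p)⁶ + 6p(1−p)⁵; the
optical-crowding regime is characterized separately and deliberately.
Problem sizes (3 seeds, 1.5k Ripley points, 39-simulation envelopes,
400-replicate crowding runs) were chosen so the whole suite runs in
seconds while keeping Monte-Carlo error well inside the asserted
tolerances.

What passing these benches does **not** show: performance on real
images (aberrations, uneven illumination, autofluorescence), dense
subcellular molecule packing (where point-graph aggregation merges
molecules and pixel-based decoding would be preferable), segmentation
quality (masks are inputs), or the true bit-error rates of any
instrument.

## Known limitations

- Point-graph aggregation merges molecules closer than the match radius;
  counts saturate at high local density (quantified by the
  optical-crowding curve).
- The specificity screen is seed-limited (no gapped or 12-mer-free hits)
  and screens the probe strand against transcript text directly.
- The thermodynamic table is DNA/DNA; DNA/RNA hybrids differ
  quantitatively.
- FOV stitching, z-stacks and multi-channel codebooks (beyond
  concatenating independent per-channel codebooks) are out of scope.
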