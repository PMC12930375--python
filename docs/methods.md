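# Methods

## Problem and model

Independent molecular-dynamics (MD) replicas of the same system evolve
asynchronously: two runs can visit the same conformational states at
different times and speeds, so frame-by-frame comparison confounds timing
with mechanism.  `netmd` compares replicas in a representation that is
insensitive to timing:

1. **Residue-contact graphs.**  Every frame is an undirected simple graph
   with one node per residue and one edge per observed residue-residue
   interaction.  Atom-level records (GetContacts-style tables) are
   collapsed to residue pairs; multiple interaction types between a pair
   within one frame count as a single unlabeled edge, because nothing
   downstream distinguishes edge types.  For coarse-grained systems,
   contacts are built geometrically: nodes are the beads within 15 Å
   (inclusive) of a mutation site, edges join node pairs strictly closer
   than 6 Å.  The node set is held constant over all frames, replicas and
   systems under comparison (the union of the shared edge vocabulary's
   endpoints, isolated nodes kept), so that per-frame graphs are
   comparable objects.

2. **Entropy filtering.**  Each contact is a presence/absence variable;
   pooling all frames and replicas of an ensemble gives its occupancy
   p and binary Shannon entropy H(p) = −p·log2 p − (1−p)·log2(1−p)
   (bits, max 1).  Contacts with H below the cutoff (default 0.1 bit,
   i.e. occupancy outside ≈ [0.013, 0.987]) are effectively invariant and
   are pruned.  An optional upper cutoff can additionally drop
   near-random contacts; it is off by default.  Filtering is applied per
   system (ensemble-specific); the union of the per-system retained sets
   defines the common edge space for the joint embedding, so that a
   contact informative in any one ensemble stays visible to all.

3. **WL document embedding.**  Each frame graph is flattened into a
   document of Weisfeiler-Lehman subtree tokens: iteration 0 emits the
   residue labels, iteration i ≥ 1 emits, per node, a 16-hex-character
   BLAKE2b digest of (previous label | sorted neighbor labels).  Three
   iterations and tokens from all iterations 0..3 are used, so residue
   identity and neighborhood shape coexist in one bag of tokens.  A
   distributed bag-of-tokens model with negative sampling (the PV-DBOW
   objective that Graph2Vec builds on) is trained jointly over all frames
   of all replicas and systems, mapping each frame to one vector in a
   16-dimensional latent space.  Joint training makes coordinates
   commensurable across systems.  Training is single-threaded with an
   internal xorshift generator, so a fixed seed gives bitwise-identical
   matrices.  PCA (retaining 90% cumulative variance by default) is
   available for visualization and diagnostics only; every alignment step
   consumes the raw 16-dimensional series.

4. **DTW alignment and DBA consensus.**  Replicas are aligned with
   dependent (multivariate) dynamic time warping: one Euclidean local
   cost over all dimensions, the classic cumulative recurrence, and a
   deterministic backtrace (ties prefer diagonal, then advancing the
   first series, then the second).  Reported scores are DTW cost divided
   by warp-path length ("normalized DTW"; divisors max(n,m) and n+m are
   configurable).  A consensus trajectory per system is computed by DTW
   Barycenter Averaging: starting from the medoid replica resampled to
   the median replica length, alternate (a) aligning every replica to the
   barycenter and (b) replacing each barycenter point by the mean of all
   frames associated to it.  Inside DBA both the alignment and the
   objective use the squared-Euclidean local cost, for which the mean
   update provably never increases the objective — the recorded
   `objective_trace` is guaranteed non-increasing.  Replica scores
   reported to the user remain plain Euclidean normalized DTW.

5. **Outlier pruning.**  The replica farthest from the consensus is
   removed while its normalized cost exceeds the next-worst by more than
   the mean adjacent gap of the sorted costs (a data-driven criterion
   that fires only when one replica clearly stands apart), recomputing
   the consensus after each removal; at least two replicas are kept.
   Fixed-count and fixed-threshold rules are also available.

6. **Clustering.**  The pairwise normalized-DTW matrix over replicas is
   clustered with Ward's linkage.  Ward on a non-Euclidean DTW matrix is
   formally a heuristic; the Lance-Williams update is applied to squared
   distances (the common "ward.D2" convention, via scipy).  The cluster
   count is selected by the largest gap between consecutive merge
   heights, or by the elbow (maximum second difference) of the height
   profile; equal heights fall back to k = 1 with a warning.  The final
   dendrogram is computed on the replicas kept after pruning (the full
   all-replica distance matrix is still written as an artifact); an
   all-replica clustering mode is exposed.

7. **Change points.**  Divergence is localized on deviation profiles.
   Three modes are exposed: the Euclidean distance of an aligned replica
   to its consensus at every barycenter index (using the warp-path
   associations); the mean local distance per frame of the first series
   when the best replica of each system (lowest normalized cost to its
   own consensus) is aligned pairwise; and the default cross-system mode,
   which aligns the two systems' consensus *barycenters* — each
   barycenter point already averages several frames of every replica, so
   this profile has the lowest noise floor and localizes weak divergence
   onsets most reliably.  Profiles are smoothed with a
   centered moving average (default window 25 frames ≈ 5% of a 500-frame
   trajectory; shrinking window at the boundaries) and segmented with
   PELT under the penalized least-squares model: minimize the sum of
   within-segment squared deviations from segment means plus β per change
   point.  β defaults to 2·σ̂²·log L with σ̂² estimated from the first
   differences of the *unsmoothed* profile (smoothing shrinks first
   differences and would understate the noise).  The PELT pruning
   condition only discards candidates that provably cannot be optimal, so
   results are exactly those of the O(n²) optimal-partitioning program.

8. **Contact shifts.**  Within a chosen window of the aligned axis, warp
   maps pull the window back to each replica's raw frames; per-edge mean
   occupancies of two groups are differenced and ranked, optionally
   restricted to edges touching a named residue (e.g. a mutation site).

A descriptor-based baseline is included for comparison: pairwise Cα-RMSD
frame matrices (least RMSD after Kabsch superposition) fed through
`dtw_from_cost`, clustered with deterministic PAM k-medoids and the
silhouette criterion.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| entropy lower cutoff | 0.1 bit | prunes contacts with occupancy outside ≈ [0.013, 0.987]; raise to 0.3 for dense graphs |
| WL iterations | 3 | neighborhood radius of the subtree tokens |
| embedding dimensions | 16 | latent space size |
| epochs / learning rate / negatives | 100 / 0.025 / 5 | PV-DBOW optimizer; exposed because no canonical values exist |
| DTW normalization | path length | divisor of the reported DTW score |
| DBA max_iter / tol | 30 / 1e-5 | convergence of the barycenter iteration |
| pruning rule | largest-gap | when to stop removing outlier replicas |
| smoothing window | 25 frames | moving-average width (must be odd) |
| PELT penalty | 2·σ̂²·log L | linear per-change-point penalty |

## Synthetic ensembles

The generator emulates the structure of multi-system MD contact data with
every hidden quantity exposed: a canonical time axis is split into latent
states (conformational regimes) by strictly increasing boundaries; each
replica observes that axis through its own monotone piecewise-linear time
warp (8 knots, Gaussian knot jitter scaled by a roughness parameter) and
may terminate up to 20 frames early; edges emit i.i.d. Bernoulli samples
of their state's occupancy, then every bit is flipped independently with
a small noise probability (0.005).

Edge occupancies are strongly bimodal, mirroring empirical contact
statistics — most contacts are almost always formed or almost never
formed, and only a minority rearranges between states:

- *invariant* edges (40%): occupancy exactly 0 or 1 in every state —
  removed by the entropy filter;
- *dynamic* edges (25%): occupancy switching between 0.95 and 0.05
  across latent states — the shared multiphase signal;
- *intermediate* edges (5%): constant occupancy in [0.25, 0.75] — noisy,
  uninformative contacts;
- *static-extreme* edges (30%): constant 0.95 or 0.05 — stable formed or
  unformed contacts that survive the filter but carry little signal.

Each variant system owns a disjoint set of condition edges (25 by
default) that are persistently formed (0.95) in the reference system and
unformed (0.05) in the variant from the second latent state onward, so
the between-system divergence has a known onset time.  One replica may be
planted as an outlier by inverting the occupancy of 30% of all edges.

The documented benchmark (`default_benchmark_spec`) is 3 systems × 5
replicas × ~500 frames over a 450-edge vocabulary on 60 residues with
three latent states — sized after a mid-size transporter study (about
500-frame replicas, a handful per condition) while staying desk-scale.

What the generator does **not** emulate: temporal autocorrelation of
contacts within a state (emission is i.i.d. given the state; real
contacts persist over consecutive frames), cooperative formation of
spatially adjacent contacts, force-field-level realism, and solvent or
lipid interactions.  Passing the recovery suite therefore demonstrates
that the pipeline identifies condition effects, outliers and divergence
onsets under known warps and realistic occupancy statistics — not that it
handles every pathology of real trajectories.

## Numerical choices

- WL digests use BLAKE2b truncated to 8 bytes — stable across runs and
  platforms, collision probability negligible at these vocabulary sizes.
- The PV-DBOW token vocabulary is ordered by sorted token string, the
  negative-sampling table follows the unigram^0.75 distribution, and
  vectors are updated in corpus order with a linearly decaying learning
  rate; no threading, so results are exactly reproducible.
- DTW backtrace tie order (diagonal > first-series step > second-series
  step) is fixed for reproducibility; costs are unaffected by ties.
- DBA stops on relative objective decrease < tol or at max_iter; a zero
  objective stops immediately (perfect consensus).
- The occupancy interval of an entropy cutoff is found by Brent root
  finding on (0, 1/2) to 1e-14.
- Degenerate inputs: empty contact input, vocabulary mismatches, even
  smoothing windows, non-positive penalties, and windows outside the
  aligned axis raise errors naming the offending value; equal-height
  dendrograms fall back to a single cluster with a warning.

## Design choices on genuinely open points

- **Edge types.**  Interaction types are retained as metadata but merged
  into unlabeled edges; type-aware graphs would change the WL vocabulary
  without a downstream consumer.
- **CG node selection** uses the first frame's coordinates for the 15 Å
  radius by default (an "any frame" mode is exposed).
- **Normalization divisor** is the warp-path length, which reduces to the
  series length for equal-length diagonal alignments; the alternatives
  are one option away.
- **Pruning stop rule** is the adjacent-gap criterion described above; a
  hard threshold and a fixed count are exposed because different
  ensembles justify different stringency.
- **Cross-system change points** default to aligning the two systems'
  consensus barycenters: a single best-replica pair carries the full
  per-frame embedding noise, and a divergence step comparable to that
  noise floor is quadratically suppressed in the Euclidean distance,
  whereas barycenter points average several frames per replica.  The
  best-replica pair mode and the replica-vs-consensus mode remain
  exposed.  The profile lives on the reference consensus axis; warp-path
  associations pull any window back to raw frames of every kept replica
  on both sides.
- **Contact-shift windows** in the pipeline default to the segment that
  opens at the first detected change point of the cross-system profile,
  contrasting all kept replicas of the two systems.

## Problem sizes

The validation suite runs entirely on synthetic data: DTW is checked
against exhaustive path enumeration on 200+ random series pairs with
lengths up to 6; PELT against the exact O(n²) dynamic program on 100
series up to length 200 over a penalty grid; the benchmark recovery runs
the full pipeline on the 3 × 5 × 500 ensemble (about five minutes of CPU,
dominated by embedding training); determinism is asserted by
byte-comparing the artifacts of two independent end-to-end runs on a
2-system ensemble.

## Known limitations

- PV-DBOW embeddings are stochastic estimators; per-frame vectors are
  noisy and only ensemble-level statistics (DTW over hundreds of frames,
  centroids) are stable.  Very short trajectories (tens of frames) embed
  poorly.
- Ward linkage and the largest-gap criterion assume the between-condition
  signal exceeds within-condition spread; weak effects (few differing
  contacts) can fall below the embedding noise floor.
- DTW is O(n·m) per pair; pairwise matrices over many long replicas grow
  quadratically in the replica count.
- The entropy filter is ensemble-global: contacts that are variable only
  inside a brief window contribute little entropy and may be pruned.
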