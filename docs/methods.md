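# Methods

## The replication model

`orimfa` models marker-frequency analysis (MFA) of an asynchronously
growing population of cells replicating a circular chromosome from
multiple origins of unequal firing efficiency.

A fraction *f* of cells (the cycling fraction) is actively replicating;
the remainder contributes exactly one genome equivalent per locus. In a
cycling cell, origin *i* fires at the start of the round independently
with probability *e&#8321;* (its efficiency). A cell in which no origin fires
cannot replicate, so the distribution over firing subsets *S* is
renormalized over non-empty subsets. Forks proceed bidirectionally from
every fired origin at constant speed *v*, so the locus at coordinate *x*
is replicated at

> t_S(x) = min_{i ∈ S} d_circ(x, o_i) / v,

where d_circ is the shortest arc on the circle. Cell ages in an
asynchronous steady-state culture follow the exponential age distribution
with density (2 ln 2 / T) · 2^(−a/T) on [0, T] for doubling time *T*;
integrating the locus copy number over that distribution gives the
per-subset expectation

> M_S(x) = 2^(1 − t_S(x)/T),

and the population marker frequency

> MF(x) = f · E_S[M_S(x)] + (1 − f), bounded by [1, 1 + f].

E_S is computed exactly by enumerating the ≤ 2^k − 1 non-empty firing
subsets (k ≤ 12 origins enforced); a seeded Monte-Carlo estimator over
sampled cells (`sample_marker_frequency`) provides the independent
cross-check used in the tests. Replication paths longer than a doubling
time (t_S(x) > T) are excluded by a validated precondition rather than
modelled: the worst reachable path is computed from the origin geometry
(half the circle for a lone fallible origin; the widest half-gap between
always-firing origins otherwise). Multi-round replication, fork stalling,
fork collisions and recombination-dependent initiation are out of scope.

### Default study conditions

The simulator defaults describe a haloarchaeal wild type:

| parameter | default | meaning |
| --- | --- | --- |
| chromosome | 2.9 Mb, circular | main chromosome |
| origins | 300 kb (e=0.9), 1300 kb (e=0.5), 2200 kb (e=0.3), 2600 kb (e=0.0) | three active origins of unequal efficiency plus one dormant origin |
| fork speed *v* | 1000 bp/min | constant bidirectional forks |
| doubling time *T* | 1812.5 min | chosen so the longest replication path takes 0.8 T |
| cycling fraction *f* | 0.5 | early-exponential culture; peak amplitude scales with *f* |
| probe design | 34 probes/kb, 50-mers, even tiling | whole-genome tiling array |
| channel noise | log-normal, sd 0.07 per channel | multiplicative intensity noise |

Deletion strains are expressed as per-origin efficiency overrides
(efficiency 0 = deleted/never fires); dormant-origin activation as a
raised override on the dormant origin.

The noise model is a per-channel multiplicative log-normal on the two
intensities (so the ratio noise sd is 0.07·√2 ≈ 0.099 in natural log).
It reproduces the qualitative property that the outlier filter (below)
discards well under 0.4% of probes. What the generator does **not**
emulate: spatial array artifacts, dye bias, GC-dependent signal,
probe-specific affinities, or sequence-level read errors — so passing
tests demonstrate correctness of the analysis chain on the model's
assumptions, not robustness to every artifact of real arrays.

## The MFA processing chain

Exactly the standard tiling-array recipe, in order:

1. per-probe ratio = exponential-phase signal / stationary-phase signal;
2. outlier exclusion: ratio > 2 or < 0.5 (strict inequalities; 2.0 and
   0.5 are retained);
3. binning: consecutive groups of 30 retained probes averaged
   (arithmetic mean of ratios) into one point located at the group's
   first probe; a trailing partial group is kept if it has ≥ 15 probes;
4. smoothing: centered 5-point moving average with 1-point slide,
   wrapping across the coordinate origin on circular chromosomes
   (linear mode shrinks edge windows symmetrically instead).

Sequencing-based profiles count read starts in non-overlapping 1-kb
windows (final short window kept with its raw count). No normalization is
applied beyond the exp/stat ratio. Two readings were genuinely open and
decided here: ratios (not log-ratios) are averaged, taking the
arithmetic-mean reading literally; and the sliding window wraps on
circular replicons, since the chromosome is a circle and wrapping keeps
the smoother mean-preserving and cardinality-preserving.

## Peak calling

Under the default conditions the profile's origin peaks are broad
(hundreds of kb) and shallow: the noiseless peak prominences are 0.224
(e=0.9), 0.029 (e=0.5) and 0.006 (e=0.3) against a per-point noise sd of
≈ 0.008 after binning and smoothing. Raw local maxima of the smoothed
track are therefore dominated by noise bumps (hundreds of candidates,
with extreme-order prominences up to ≈ 0.06). `call_peaks` works at two
scales:

* **Detection** on a triangularly re-smoothed copy of the profile
  (kernel half-width 60 kb by default). Triangular smoothing shrinks
  noise-bump prominences roughly tenfold while real peaks, being much
  wider than the kernel, keep theirs. Candidates are local maxima whose
  prominence (peak height minus the higher of the two flanking minima,
  walking each way until a strictly higher point, wrapping on circles)
  clears the threshold; the default threshold is 5 × MAD of the input
  profile's successive-point differences. Accepted calls are greedily
  thinned so no two lie within 100 kb (keeping the higher).
* **Localization** by a zero-sum matched filter — the triangular kernel
  minus a boxcar of twice its width. This kernel is symmetric with zero
  sum, so it is exactly insensitive to constant, linear and quadratic
  background, which otherwise drags the apex of a broad smoothed peak
  tens of kb toward a stronger neighbour. The call is anchored at the
  matched-filter maximum near the detection and snapped to the highest
  profile point in a small neighbourhood; on a noiseless profile this
  lands on the true apex (within one binned-point spacing).

Positional accuracy has a hard limit set by the data, not the algorithm:
with ratio noise 0.099 per probe, 34 probes/kb, and a cusp slope of
about 2–4 × 10⁻⁷ per bp (as implied by f = 0.5 and the 0.8 T fork
kinetics), the Cramér–Rao bound for locating an origin from all probes
in its skirt is ≈ 1.6 kb (e=0.9), 2.9 kb (e=0.5) and 4.8 kb (e=0.3) per
realization. In practice the caller localizes the strongest origin to
within ≈ 10–20 kb under default noise, consistent with the 20-kb default
`match_tolerance` used when pairing peaks with annotated origins. The
weakest default origin (e=0.3, noiseless prominence 0.006 ≈ one third of
a single point's noise sd) is not reliably detectable at default noise
at all; strain comparisons that depend on complete peak sets should be
interpreted accordingly, and borderline calls are left to the exposed
threshold (`min_prominence`, `min_separation`, `kernel_halfwidth_bp` are
all configurable).

Relative firing efficiency is estimated as peak height above the profile
minimum, normalized to sum to 1 across peaks. Deliberately simple — a
forward-model fit would be more efficient but is excluded from this
version so the estimate stays independently testable; on noiseless
profiles the estimated efficiencies rank identically to the simulated
ones.

Strain comparison labels each known origin *active* (peak in parent and
mutant), *lost* (parent only), *activated* (mutant only) or
*unchanged-absent* (neither), with unmatched mutant peaks reported as
novel; swapping the roles of parent and mutant exchanges *lost* and
*activated*. A sequence-predicted origin with no matched peak is
classified *dormant*.

## Sequence-based origin prediction

Archaeal origins typically lie in the intergenic region immediately
upstream of an `orc1/cdc6` initiator gene and carry a pair of
origin-recognition-box (ORB) repeats in inverted orientation. The
predictor applies that rule mechanically:

1. extract the strand-aware upstream intergenic gap (to the nearest
   neighbouring gene, truncated at 2 kb);
2. find all maximal repeated 18–35 bp substring pairs within the region,
   on either strand, tolerating up to `max_mismatch` mismatches
   (default 3). This is an exhaustive seed-and-extend scan over
   diagonals with cumulative-mismatch run detection — for ≤ 2-kb regions
   exhaustive search is tractable and exactly verifiable against an
   all-substring-pairs oracle, which an expectation-maximization motif
   model would not be;
3. keep motifs whose consensus carries a G-string — a run of ≥ 4
   consecutive G on either strand (the G-run length is configurable;
   the hallmark is conventional but its exact length is not
   standardized, so 4 is a calibration choice);
4. keep loci where qualifying motif instances occur on both strands (an
   inverted pair); each surviving cdc6 gene yields one origin
   prediction, and failing genes are reported with the failing step.

Origin conservation across genomes is scored through the initiator
protein: percent identity from a global alignment under BLOSUM62 with
affine gap cost 11 + g (identical columns / all alignment columns,
gaps counted), orthology called above 80%. Global-alignment identity
uses a different denominator than local-alignment tools, so the 80%
threshold is exposed in configuration.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere internally; GFF3's
  1-based closed convention is converted only at the I/O boundary. BED
  and bedGraph are written natively.
* All stochastic outputs are pure functions of (inputs, seed); the
  pipeline report carries the seed and a SHA-256 hash of the canonical
  YAML configuration.
* Subset enumeration is capped at 12 origins; beyond that the Monte-Carlo
  estimator is the intended tool.
* In `estimate_efficiency`, a profile whose peaks all sit at the global
  minimum is rejected rather than returning 0/0.
* Reads whose body would cross the circular coordinate origin are
  written with their end capped at the chromosome length (BED cannot
  express a wrapped interval); only read starts enter the windowing.
* Test problem sizes: Monte-Carlo cross-checks use 200,000 sampled
  cells; noisy parameter-recovery runs use 20 seeded replicates of the
  full 2.9-Mb array; repeat-search oracle comparisons use 50 random
  regions up to 1 kb.

## Known limitations

* Efficiency estimates are height-based, not model-fit; they are
  rank-faithful but not calibrated to absolute firing probabilities.
* The weakest-origin detection limit described above: peak sets from
  low-amplitude profiles (small *f*, low efficiency) are incomplete by
  the physics of the measurement.
* The repeat search reports motifs with exactly two instances per
  maximal pair; families with three or more copies appear as multiple
  overlapping pairs collapsed by footprint, not as one multi-instance
  motif model.
* Replication-termination inference, fork-velocity estimation and
  origin-timing analysis are out of scope.
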