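# Methods

## Model and procedure

`kmercorrect` assumes substitution-only sequencing errors that are
independent across read positions, with per-base error probabilities
estimated by the Phred quality string (`q = 10^(-Q/10)`). Reads are
decomposed into k-mers; k-mers containing an uncertain base (N) are
discarded, and that is the only masking mechanism — the FASTQ parser maps
every non-ACGT character to N so nothing else needs to handle alien
symbols.

**Statistics (Step 1).** For each distinct k-mer x the pipeline keeps
`count_x`, the per-position log error products
`log error_x[j] = Σ_occurrences log q_r[i+j]`, and the derived quality.
Combining occurrences multiplicatively encodes the assumption that
independent observations of the same base are independent evidence: a
21-mer seen three times at Phred 20 already has per-position combined
error 10⁻⁶. Products are accumulated in log-space because they underflow
double precision once counts pass ~150. The per-k-mer *quality* (the
probability that the k-mer contains an error) has no standalone closed
form separate from the error-free probability, so it is defined as
`quality_x = 1 − p_x` with `p_x = Π_j (1 − exp(log error_x[j]))`.

**Hamming components (Step 2).** Components of HG_τ(X) are found by the
pigeonhole argument: split `[0, k−1]` into τ+1 parts; any two k-mers at
distance ≤ τ agree on at least one part. Blocks of k-mers equal on a part
are found by sorting packed 2-bit codes; blocks larger than
`max_quadratic` are re-split with a second, strided partition, and
whatever remains is compared pairwise regardless. Exactly two partition
families are used (contiguous, then strided): a deeper recursion would
need ever more partition families while the two-level scheme is already
exact — the fallback pairwise scan only costs time, never correctness —
and the oracle-equivalence tests exercise `max_quadratic` down to 2.
When τ+1 does not divide k, parts of size ⌈k/(τ+1)⌉ and ⌊k/(τ+1)⌋ are
used; the pigeonhole argument is unaffected. Union-find is
`scipy.cluster.hierarchy.DisjointSet`; components are emitted sorted by
smallest member so output never depends on processing order.

**Subclustering (Step 3).** Within a component, the likelihood that
member x arose from center c multiplies `q_x[j]` at mismatching and
`1 − q_x[j]` at matching positions; the maximum-likelihood center of a
cluster is its count-weighted consensus string. The number of clusters m
is chosen greedily: m-means (over Hamming distance, centers re-estimated
as consensus) is run for m = 1, 2, 3, … and the BIC-penalized objective
`ℓ_m = 2 log L_m − (3km + m − 1) log N` accepted while it increases.
The parameter count is m−1 mixture weights, km center letters and 2km
conditional error probabilities. Two deliberate readings of ambiguous
conventions, both exposed as flags:

* **N is the multiset size** (total occurrence count of the component),
  and the log-likelihood is count-weighted to match — each read
  occurrence is one observation. `bic_distinct=True` switches both to
  distinct-k-mer counting.
* **The penalty applies at every m including m = 1** (`ℓ_1` is penalized
  by `3k·log N`). BIC comparisons are only meaningful when every model is
  penalized by the same rule; since the penalty difference between
  consecutive m is what drives the stopping decision, leaving `ℓ_1`
  unpenalized would silently shift the splitting threshold.

Natural logarithms throughout. m-means initialization takes the m members
with the highest error-free probability p_x (ties: higher count, then
lexicographic); assignment ties go to the lowest-index center, consensus
ties to the alphabetically first base; an empty cluster is reseeded with
the member farthest from its current center; iteration stops when an
assignment repeats or after 100 rounds. These tie-break rules exist to
make the whole pipeline bit-reproducible, not because the choices matter
statistically.

**Solid selection and expansion (Steps 4–5).** A cluster is trusted when
`p_C = 1 − Π(1 − p_x) > solid_threshold`; its center enters the solid
set. Singletons get no special treatment — a singleton's p_C is just its
p_x. Consensus centers that never occur in the reads are appended to the
index as synthetic entries (count 0) whose per-position error products
aggregate the members that agree with the center at each position; they
can vote during correction but never cover read positions during
expansion, because coverage is defined over observed occurrences.
Expansion then runs to a fixed point: a read whose every position lies
inside at least one solid k-mer occurrence has all its k-mers promoted.
Each pass evaluates coverage against the solid set frozen at the start of
the pass, which makes both the fixed point and the pass count independent
of read order. A read's own non-solid k-mers do not block coverage as long
as solid occurrences span every position.

**Correction (Step 6).** Per read position, solid k-mer occurrences vote
their own letter and non-solid occurrences whose cluster center is solid
vote the center's aligned letter `x[j−i]`. The argmax base wins; when the
original base ties with the maximum it is kept, and zero-vote positions
are never touched — so the corrector cannot alter bases it has no
evidence about, and read length is always preserved. Corrected bases keep
their original quality characters, which keeps the FASTQ fields aligned
and preserves the information that the base was uncertain.

**Iteration.** The pipeline reruns while ≥ 0.2% of reads changed in the
last pass, up to 3 iterations. Both values are configurable; "substantial
amount of changes" has no canonical quantification, and in practice the
second iteration already changes an order of magnitude fewer reads than
the first.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 21 | k-mer length; standard for bacterial-scale short-read correction, small enough to fit a 2-bit packed 64-bit code |
| `tau` | 1 | Hamming-graph edge threshold; the cheapest sound setting, configurable 1–2 |
| `solid_threshold` | 0.999 | cluster quality p_C required for a solid center; deliberately strict so only well-attested centers seed correction |
| `change_fraction_stop` | 0.002 | stop iterating below 0.2% of reads changed |
| `max_iterations` | 3 | upper bound on pipeline iterations |
| `max_quadratic` | 1000 | largest block processed pairwise before the strided re-split (~5·10⁵ comparisons per block) |
| `epsilon` | 0.01 | per-position error rate of the uniform-error compatibility model (`hammer_likelihood`) |
| clamp | [10⁻¹⁰, 1−10⁻¹⁰] | error probabilities are kept strictly inside (0,1) so log-space products never collapse |
| `phred_offset` | 33 | FASTQ dialect; 64 available for legacy Illumina data |

`hammer_emulate=True` skips subclustering (one consensus center per
component) and `no_expansion=True` skips Step 5; together they reproduce
the simpler single-center corrector as ablations. `canonical=True` merges
each k-mer with its reverse complement (representative = min of the
pair); the default keeps strands separate, which costs nothing on the
synthetic fixtures because both strands are sampled deeply.

## Synthetic data

The generator emulates the regime the method is designed for: a random
genome (optionally with planted near-identical repeat pairs at a stated
Hamming divergence, the case that makes subclustering necessary), read
start positions drawn from a smoothly varying lognormal amplification
profile (`sigma=1`, correlation length 500 bp; `sigma=0` degenerates to
uniform, multi-cell-like coverage), both strands, and per-base qualities
drawn around Phred 20 (sd 3, clipped to [2, 41]) with substitutions
injected at exactly the emitted `10^(-Q/10)` — so quality strings are
calibrated by construction, and the calibration is itself tested.
Errors pick one of the three alternative bases uniformly.

What the generator does **not** model: indels, chimeric/contaminant
fragments, paired-end structure, position- or context-dependent error
profiles, and miscalibrated quality strings. Passing the end-to-end tests
therefore demonstrates the machinery under the model's own assumptions —
honest qualities and substitution-only errors — not robustness to every
artifact of real libraries.

Default study conditions for the end-to-end experiment: 10 kb genome,
3 000 reads of 100 bp (~30× mean coverage), ~1.3% realized base error
rate. At these settings the corrected error rate is typically 50–70×
lower than the input rate. The ten-seed robustness check in the unit
suite runs the same regime on a 3 kb genome (900 reads) to keep the suite
fast; the 10 kb configuration is exercised once in the acceptance test
and in `scripts/acceptance.py`.

## Numerical and degenerate-input choices

* All probability products are log-space sums; `log1p`/`expm1` are used
  near 0 and 1.
* The disk-bucketed counting path reproduces in-memory counts bit-exactly
  and log-aggregates to 10⁻⁹ (summation order differs); its hash is the
  packed k-mer code modulo the file count, stable across runs.
* Reads shorter than k contribute no k-mers, are never expansion
  candidates and pass through correction unchanged. Empty inputs yield
  empty indexes and no components.
* A k-mer lands in exactly one subcluster; `center_of` is total. When a
  consensus center coincides with an observed k-mer that belongs to a
  different cluster, that k-mer keeps its own cluster's center while
  still becoming solid if the cluster it centers qualifies.

## Limitations

* Substitution-only: the Hamming metric cannot express indels.
* No coverage-based filtering is attempted even when coverage *is*
  uniform, so the corrector never discards uncorrectable reads; quality
  trimming (`trim_quality`) is an optional post-step, off by default.
* Errors in regions covered at ≤ 2× are usually uncorrectable: the
  corresponding k-mer clusters cannot reach the solid threshold, and
  expansion has nothing to extend from. The zero-vote rule means such
  regions pass through untouched rather than being damaged.
* Two errors closer than k bases within the same read are corrected only
  when each has covering k-mers free of the other; three clustered errors
  typically survive.
* The subclustering observation model treats occurrences as independent,
  which overstates evidence when duplicate reads are PCR copies rather
  than independent molecules.
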