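# Methods

## The workflow being modelled

In situ barcoding of restriction-digested chromatin lets many samples share
one immunoprecipitation: chromatin is cut inside nuclei by a 4-base-cutter
restriction enzyme, a sample-specific adaptor is ligated onto the fragment
ends, and the barcoded nuclei are pooled. After sequencing, each mate of a
read pair carries a fixed technical prefix — a 4-nt unique molecular
identifier (UMI) followed by an 8-nt sample barcode — ahead of the genomic
insert. Downstream processing therefore needs four computational stages:
barcode-set design, demultiplexing, pool-balance QC, and UMI-based duplicate
removal. This package implements those stages plus a generative simulator
that produces inputs with known ground truth.

## Barcode design

The adaptor chemistry fixes barcode length (8 nt) and composition (exactly
4 of 8 bases G/C; "50% GC" is read as exact, not approximate). Composition
alone gives `C(8,4)·2⁸ = 17,920` candidates. Design adds three constraints
that the chemistry does not fix but that make the code *usable*:

- **Pairwise Hamming distance ≥ 3** (default). A code with minimum distance
  `d` assigns any observed barcode with ≤ m substitutions unambiguously iff
  `d ≥ 2m + 1`; distance 3 therefore licenses one-mismatch demultiplexing
  with zero cross-assignment risk from single errors. This is standard
  code-design practice; the original 60 published barcodes are not printed
  anywhere, so the designer regenerates constraint-compatible sets rather
  than reproducing them.
- **Maximum homopolymer run 2** (default), avoiding the most
  error-prone synthesis/sequencing contexts.
- **Forbidden motifs**, defaulting to the simulator's restriction site
  (`GATC`) so a barcode cannot recreate a cut site at the ligation junction.

Selection shuffles the candidate pool with a seeded generator and greedily
accepts each candidate at distance ≥ 3 from everything accepted so far. The
greedy pass is deterministic per seed, reaches ~550–600 barcodes from the
filtered pool of 14,241 (far above the 96-barcode plate capacity), and an
infeasible request fails loudly, reporting the maximum achievable size.
Greedy selection yields a *maximal* set, not the maximum clique — adequate
here because requirements top out at 96.

## Demultiplexing

Both mates are split as `[UMI, barcode, insert]`; the combined fragment tag
is mate 1's UMI followed by mate 2's (the order is a convention and is fixed
and documented here because the tag must be reproducible downstream). The
tag is appended to the read name as `<name>_<umi>`, the convention
UMI-aware deduplicators parse back out of the SAM query name.

Barcode matching returns the unique set member within `max_mismatch`
substitutions; `N` counts as a mismatch, ties at minimal distance are
*ambiguous* and unassigned. `max_mismatch` defaults to 1 when the set
declares `min_hamming ≥ 3` and to 0 otherwise, so the default is always
sound. For tolerance ≤ 1 matching is a precomputed dictionary over all
Hamming-≤1 neighbourhoods (O(1) per read); larger tolerances fall back to a
memoised linear scan.

Because the adaptor ligates to both fragment ends, both mates carry the same
sample's barcode; the default mate policy (`both-agree`) requires both mates
to resolve to the same sample and routes disagreements to
`mate_conflict` — the strict choice that minimises sample bleed-through. An
`either` policy (accept on a single resolving mate) is available for
lower-quality runs. Assigned pairs are trimmed by the 12-nt prefix (qualities
in lockstep); undetermined pairs are written untouched so the failure mode
remains diagnosable. Output read counts always satisfy conservation:
assigned + undetermined = input.

## Balance QC and depth estimation

Per-barcode percentages are computed over barcode-assigned pairs by default
(with an option to include the undetermined pool as its own category). The
mean of category percentages is identically `100/n`, so imbalance shows up
in the standard deviation and in the min/max fold-deviation from uniform,
not in the mean. Both population (ddof=0, the reported value) and sample
(ddof=1) standard deviations are emitted, since a "±" on a published spread
rarely says which was used.

Depth estimation uses plug-in fractions from a shallow run: with observed
fraction `f_i = c_i / Σc`, the rarest barcode dictates
`total = ceil(s · m / min_i f_i)` for a per-sample floor of `m` read pairs
and safety multiplier `s` (default 1.0; no sampling-uncertainty inflation is
applied beyond it). A barcode with zero observed reads makes the estimate
undefined and raises, naming the barcode — no finite depth can guarantee its
coverage.

## UMI deduplication

Aligned pairs are first filtered to `mapq > 3` (strict inequality). The
pair's mapq is taken as the minimum over its two mates — the conservative
reading when a published filter names a per-pair threshold without saying
which mate it applies to. Unmapped, secondary and supplementary records are
skipped before pairing; coordinates are 0-based half-open internally, and
soft-clipped bases are *not* un-clipped when computing the fragment span
(a documented divergence knob from aligner-specific conventions).

Grouping uses the full fragment interval plus orientation — paired-mode
grouping, appropriate because restriction-defined fragments make both ends
informative. Within a group:

- `exact`: one representative per distinct UMI (the brute-force oracle);
- `directional` (default, mirroring the common deduplicator default): build
  the directed adjacency `u → v` iff `Hamming(u, v) ≤ umi_mismatch`
  (default 1) and `count(u) ≥ 2·count(v) − 1`, then walk components from the
  highest-count seeds; each component keeps one representative. The count
  condition lets an abundant parent absorb its one-off sequencing-error
  derivatives while two comparably abundant UMIs stay separate. Note the
  rule merges two *singleton* neighbours (1 ≥ 2·1−1), so directional counts
  are a lower bound on exact counts.

Representatives are the first record of each cluster in input order, making
the operation deterministic and idempotent for a fixed input order.

## Simulator

The generative model follows the protocol stage by stage: digest the
reference at every (possibly overlapping) IUPAC-motif match, cutting at
`match_start + cut_offset`; draw a sample by pool weight and a fragment
uniformly (multiplied by a fold inside optional enrichment intervals); draw
fresh UMIs uniformly over `4^umi_len` per mate; emit mate 1 as
`umi1 + barcode + fragment 5'` and mate 2 as
`umi2 + barcode + reverse-complement 3'`, both truncated to the read length
(default 50 bp, matching short-read pairs); re-emit an earlier pair — same
fragment and UMIs — with probability `pcr_duplicate_rate`; and apply i.i.d.
substitution errors per emission, so duplicates differ only by noise.

Defaults encode the study conditions the package is exercised under: motif
`GATC` with `cut_offset 0` (the enzyme behind a published "4-cutter" is
typically unnamed; a degenerate `RGCY`/offset-2 preset ships for
CviKI-1-like digestion), read length 50, 4-nt UMIs, 8-nt barcodes, constant
`I` (Q40) qualities, substitution-only errors. The reference is a seeded
random toy genome (two 20–50 kb contigs for tests; `GATC` occurs every
~256 bp in random sequence, giving realistic fragment lengths relative to
the 38-nt post-trim insert).

A truth sidecar records, per emitted pair, the sample, the error-free
combined UMI, the fragment interval and the duplicate lineage; a
truth-derived SAM (perfect alignments reconstructed from fragment
coordinates, named as the demultiplexer would name them) stands in for the
alignment stage when exercising deduplication. It is a test harness, not an
aligner.

**What the simulator does not model** — and hence what passing tests do not
establish about real data: fragment-length and ligation-efficiency bias,
adapter read-through on fragments shorter than the read (reads are truncated
at the fragment end instead), indels, quality-score structure, chromatin
state, antibody efficiency, and real mapping ambiguity (the truth SAM has
uniform mapq). Tests demonstrate algorithmic correctness against known
truth, not protocol performance.

## Numerical and interface choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs
  (gzip members are written with `mtime=0` for this reason).
- Percentages and rates are plain floats; the only rounding applied is in
  report formatting (4 decimals in TSV output).
- Degenerate inputs fail loudly rather than silently: empty candidate
  pools, infeasible set sizes, all-zero count vectors, zero-coverage
  barcodes in depth estimation, mates shorter than the prefix, R1/R2
  desynchronisation, inconsistent UMI lengths, `read_len ≤ prefix_len`.
- Problem sizes used by the bundled checks: the balance measurement
  simulates 600,000 pairs over 60 samples (mean percentage is then an
  algebraic identity and its spread purely multinomial/sequencing noise);
  unit tests run at 10²–10⁵ pairs, chosen so the whole suite stays
  interactive while keeping binomial assertions inside 3-sd bands.

## Known limitations

- Greedy selection gives no guarantee of reaching the true maximum code
  size; it is deterministic per seed and comfortably exceeds 96.
- Replicate-to-replicate spread of real barcode representation (wet-lab
  ligation variability) is not reproducible from simulation; the package
  reports the statistics but the published replicate values require the
  deposited sequencing data.
- Demultiplexing assumes both mates are present and layout-identical;
  single-end RELACS data is out of scope.
- The deduplicator targets algorithmic equivalence with the directional
  method as published, not behavioural equivalence with any specific tool
  version.
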