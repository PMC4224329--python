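# Methods

`palaeomito` implements the standard inference chain for authenticating and
placing an ancient human mitochondrial genome from short-read data:
simulation of degraded reads, iterative reference-guided assembly of a
circular consensus, deamination damage profiling, diagnostic-position
contamination estimation, and hotspot-masked haplogroup/phylogenetic
placement. This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic data do and do not emulate.

## Coordinate frame and variant model

All positions are 1-based inclusive on a circular reference frame
(by convention 16,569 bp, the length of the standard human mtDNA
reference); arithmetic wraps modulo the frame length. The package uses a
substitution-only model: every genome it handles is expressed in reference
coordinates at full frame length, variants are single-base substitutions
written `<ref><pos><alt>` (e.g. `C10822A`), and indels are out of scope.
This matches how mtDNA haplogroup-defining variants are conventionally
written and makes multiple alignment unnecessary — genomes in one frame
are column-aligned by construction. Conversion to 0-based half-open
coordinates happens only inside the aligner.

The hypermutable regions conventionally excluded from mtDNA phylogenetics
are bundled as the standard hotspot mask: the poly-C runs 303–315 and
16182–16194, the AC repeat 515–525, and site 16519. On the 16,569-position
frame this leaves 16,531 analyzable positions genome-wide. The
coding-region window is fixed at 577–16023 inclusive, within which the
mask removes nothing and 15,447 positions remain; this window follows
standard mtDNA practice (control region = 16024–576 across the origin).

The bundled reference is a deterministically generated synthetic sequence
(uniform base composition, fixed internal seed) pinned so that the
reference base at every variant position used by the bundled fixtures
matches its label (C at 10822, G at 3591, T at 408, …). It is a test and
demonstration frame, not a biological sequence; any real reference of the
same conventions can be substituted.

## Read simulation

The simulator emulates a heavily degraded single-source mtDNA library:

* **Fragmentation.** Fragment start uniform on the circle, strand uniform,
  lengths log-normal with configured mean/SD (defaults 50 ± 10 nt,
  matching severely fragmented ancient material; a "rib-like" library uses
  56 nt), truncated to [20, frame length]. Truncation at 20 keeps reads
  seedable; at the default mean the truncated mass is negligible, so
  sample moments recover the configured values.
* **Terminal deamination.** Post-mortem cytosine deamination is modeled on
  the sequenced strand after strand selection: a C at distance *i* from
  the 5′ end is read as T with probability `baseline + p5_max·exp(−decay·(i−1))`,
  and symmetrically G→A from the 3′ end. The exponential decay is the
  standard single-strand-overhang approximation. Defaults
  `p5_max = p3_max = 0.40`, `decay = 0.3`, `baseline = 0.001` emulate a
  terminal conversion rate above 35%, the regime typical of authentic
  ancient samples. Because damage is applied to the read strand,
  minus-strand reads carry the complementary pattern in reference
  coordinates, exactly as read-oriented damage profiles observe it.
* **Sequencing error.** Per-base Phred qualities are drawn
  normal(mean 35, SD 3), clipped to [2, 41]; each base is substituted
  uniformly among the other three with probability `10^(−q/10)`. An
  error-free switch exists for exactness contracts in tests.
* **Contamination.** Each read is independently drawn from a divergent
  "modern contaminant" genome with the configured probability, so the
  contaminant read count is binomial.

One global seed drives independent per-stage generators (fragmentation,
contamination, damage, quality, error), so toggling one stage leaves the
draws of the others unchanged, and a fixed seed yields byte-identical
FASTQ output. A truth table records per read its source, placement,
strand and damaged offsets, enabling parameter-recovery tests.

What the simulator does **not** emulate: library-preparation chemistry
differences (single- vs double-stranded protocols), PCR duplicates beyond
coincidental start/end collisions, index hopping, nuclear mitochondrial
insertions (NUMTs), heteroplasmy, or indels. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative model, not robustness to every artifact of real libraries.

## Alignment and iterative assembly

Reads are placed on the circular reference by ungapped alignment:
exact k-mer seeding (k = 12) proposes offsets for the read and its reverse
complement, every seeded offset is scored in full (match +1, mismatch −1),
and the best placement wins; circularity is handled by scoring against the
reference extended with wrap bases and reporting coordinates modulo the
length. Damage-aware scoring reduces the mismatch penalty for the two
deamination-consistent mismatch types in reference frame (read T over
reference C, read A over reference G — which covers both strands): full,
half (default) or zero penalty are selectable. If exact seeding produces
no acceptable placement, seeding is retried with damage-folded k-mers
(C≡T, G≡A), which rescues heavily deaminated reads whose every exact
12-mer was destroyed; under the stylized uniform-damage regime
(decay = 0, 35% conversion) roughly a third of reads need this fallback,
while under decaying damage it is almost never used. A placement is
accepted if its score reaches a configurable fraction (default 0.3) of
the perfect score; ties are broken deterministically (higher score, plus
strand first, smaller start). An exhaustive all-offset scorer with
identical selection rules serves as the test oracle.

Assembly then iterates the classic loop: align all reads to the current
reference → collapse reads sharing (start, end, strand) into unique
molecules (PCR-duplicate removal; the representative takes, per position,
the highest-quality base among duplicates) → call a consensus by
summed-quality argmax per position → use the consensus as the next
reference, until two successive consensus sequences agree or a cap
(default 10 rounds) is reached. Numerical conventions: consensus ties go
to the current reference base if tied, else to the alphabetically first
base; positions covered by fewer than `min_depth` unique molecules
(default 2, reflecting the practice of not calling positions seen by a
single read) are reported as N; and the convergence comparison ignores
positions that are N in either iterate, which prevents oscillation at
marginal-depth sites. The assembly report carries read/molecule counts,
the on-target fraction, and coverage in both conventions found in the
literature (per unique molecule and per raw aligned read).

## Damage profiling

For each aligned molecule, positions within a window (default 25 nt,
typical practice for damage plots) of each molecule end are tabulated as
(reference base X, read base Y) observations indexed by distance from
that end; minus-strand molecules are re-oriented read-wise (right edge =
5′ end, bases complemented) before tabulation. The frequency of X→Y at
distance *d* is the Y count over the reference-X opportunity count; cells
with zero denominator are NaN, never 0. Profiles are additive over
partitions of the read set, which the tests exploit. Profiling against
the final consensus (the default in the pipeline) keeps true variants
from inflating apparent damage; profiling against the initial reference
is available to mimic raw-read damage plots. The terminal summary reports
the distance-1 5′ C→T and 3′ G→A frequencies (plus distance 1–3 means,
since "terminal" is sometimes read as the first few bases) and flags the
library aDNA-consistent when both reach a threshold (default 0.10).

## Contamination estimation

Diagnostic positions are sites where at least a threshold fraction
(default 0.99) of non-N panel bases agree on one base that differs from
the sample's base; sites where the sample is N are skipped rather than
guessed. Each (molecule, covered diagnostic position) observation is
classified clean (sample base), contaminating (panel-consensus base) or
other (any third base or N). The estimation unit is the observation, not
the molecule, because coverage counts at diagnostic panels are
conventionally reported as sequences covering the positions; "other"
observations are excluded from the denominator since only the two
informative states are defined. The contaminating fraction gets a Wilson
score interval

    (p̂ + z²/2n ± z·√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)

whose upper endpoint is the conservative headline bound; the Wilson form
is chosen for its correct behavior at and near k = 0. The z quantile is
computed from the confidence level (default 0.95) rather than hard-coded.
With 4 contaminating observations of 1,678 the 95% upper bound is 0.6%,
and with 0 of 391 it is 1.0% — the package's acceptance checks pin both.

## Haplogroup classification and trees

Classification walks a defining-variant tree from the root: a child is
entered when the genome carries at least a configurable fraction (default
0.8; exact mode available) of the child's *assessable* defining variants,
where masked sites and genome-N sites are excluded from the denominator —
this tolerates incomplete consensus genomes without letting missing data
qualify a clade on its own (a child with no assessable variants never
qualifies). If two children qualify, both are reported and the call is
flagged ambiguous at the parent. The bundled mini-tree contains only an
L0d2c → L0d2c1 → {a, b, c} backbone; the two variants defining the
terminal c-subclade are the published pair (C10822A, C16355T), while the
upper clades carry synthetic stand-in variants (real defining sets are
not reproduced here). Trees are plain TSV (`node, parent, variants`) so
users can supply fuller nomenclatures.

Pairwise comparison and p-distance matrices exclude masked positions and
positions N in either genome; similarity is 1 − diffs/compared. Private
variants of a focal genome are unmasked positions where it differs from
all other clade members while those agree among themselves, labelled
shared-base→focal-base.

Tree building is neighbor joining (Q-criterion pair selection, standard
limb-length and distance-update formulas), exact on additive matrices and
fully deterministic: selection ties are broken by the smallest leaf label
in each subtree. NJ was chosen over approximate-ML because the package's
topological claims at fixture scale (clade membership, sister
relationships) are NJ-recoverable and NJ is completely specified, hence
testable against an independent implementation and against the generating
tree of an additive matrix. Output is Newick; with an outgroup given, the
tree is rooted at the midpoint of the outgroup's pendant edge. Branch
lengths are not clamped at zero: the fixture genealogy genuinely contains
a zero-length edge (one contemporary genome carries no private variants,
so it sits at its clade's ancestral node), and NJ's resolution of that
polytomy is tie-broken, not data-driven — accordingly the tests assert
clade monophyly, not the arbitrary resolution inside the polytomy.

## Pipeline

The pipeline runs simulate → assemble → damage → contam → classify → tree
with plain-file handoffs (FASTA/FASTQ/TSV/JSON) and no in-process-only
state. A manifest records the seed, the normalized configuration and a
SHA-256 checksum of every stage output; stages re-hash their declared
inputs before use, so tampered intermediates fail loudly, re-running a
configuration is byte-identical, and a deleted downstream output can be
regenerated alone. Configurations are schema-checked with aggregated,
path-qualified errors; a seed is mandatory whenever simulation is enabled.

## Problem sizes in the test suite

Simulation-based checks use library sizes chosen to give comfortable
statistical resolution at interactive runtimes: 50,000 reads for terminal
damage-rate recovery (≈12,500 distance-1 cytosine opportunities, binomial
3σ ≈ 1.3 percentage points), 5,000–6,000 reads (≈15–18× coverage) for
assembly convergence and library-concordance checks, and 12,000 reads
(≈1,000–1,800 diagnostic observations) for contamination recovery at 5%.
The published study's own coverage figures (≈103× and ≈21×) are not
recomputable without its undeposited raw reads; the assembler's checks
are therefore property-based (oracle equality, convergence to a known
truth, concordance of independent libraries) rather than numerical
replays.

## Known limitations

Substitution-only throughout (no indels, no heteroplasmy); ungapped
alignment; no NUMT/mappability filtering; no likelihood-based consensus,
authenticity scores or mixture-model contamination estimators; the
haplogroup mini-tree is a scaffold, not a nomenclature; radiocarbon
calibration is out of scope.
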