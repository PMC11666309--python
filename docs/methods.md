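# Methods

`bitevol` is an individual-based, forward-in-time model of genome-architecture
evolution.  Each organism is a circular, double-stranded binary genome; a
deterministic genotype-to-phenotype map turns the sequence into a fitness; a
spatial Wright–Fisher cycle with seven mutation operators evolves a fixed-size
population.  The package exists to study how population size N and per-base
mutation rate μ shape genome size and coding density, and in particular the
role of *replicative robustness* — the probability that an offspring inherits
exactly its parent's fitness — as the indirect selective force behind genome
streamlining.

## The genotype-to-phenotype map

Decoding is a pure function of the genome sequence and proceeds in four
stages, evaluated identically on both strands (the lagging strand is the
reverse complement of the stored bits):

1. **Transcription.**  Every 22-bp window within 4 Hamming mismatches of the
   promoter consensus `0101011001110010010110` starts a transcript with
   expression level `e = 1 − d/5` (d = mismatch count).  The transcript runs
   to the first downstream stem-loop terminator: positions `i..i+3` equal to
   the reversed complement of `i+7..i+10` (4-bp stem, 3-bp loop).  A promoter
   whose strand carries no terminator produces no RNA.
2. **Translation.**  Within a transcript, every occurrence of the
   Shine-Dalgarno-like motif `011011`, a free 4-bp spacer and the START codon
   `000` opens a reading frame, read 3 bits at a time until the STOP codon
   `001` in frame; frames without STOP inside the transcript are discarded.
3. **Protein functions.**  The functional codons of a gene carry one bit each
   for three parameters: `100/101` → m, `010/011` → w, `110/111` → h.  Each
   parameter's bit string is read as a Gray-coded binary fraction and mapped
   to m ∈ [0,1] (kernel position), w ∈ [0, 0.033] (half-width), h ∈ [−1,1]
   (height).  A parameter with no codons takes its default (m=0.5, w=0, h=0);
   proteins with w=0 or h=0 are non-functional and dropped.
4. **Phenotype and fitness.**  Each protein contributes a triangle kernel of
   height `h·e` at m with half-width w.  Kernels are summed on a uniform grid
   of D = 1,024 points over [0,1], clipped to [0,1].  The metabolic error g
   is the trapezoidal integral of |phenotype − target| and fitness is
   `exp(−k·g)` with selection strength k = 1,000 by default.

The environmental target is a fixed sum of three Gaussians
(center, height, sd) = (0.25, 0.6, 0.05), (0.53, 0.8, 0.04), (0.80, 0.5, 0.03),
clipped to [0,1].  It is an arbitrary but pinned choice of a multi-peaked,
non-trivial target; its integral (≈0.193) is the metabolic error of an empty
phenotype and therefore the fitness floor.

Protein kernels are summed in a canonical order (sorted by (m, w, h, e)), so
that decoding is not only deterministic but invariant — bit-for-bit in the
metabolic error — under rotation of the circular genome and under
reverse-complementing it.  This matters because neutrality is defined as
*exact* equality of metabolic error (no epsilon): with a canonical, pure
evaluation, "exactly the parent's fitness" is a well-defined event.

**Coding definition.**  A position is *coding* iff it lies in at least one
translated CDS (START through STOP inclusive) of an expressed protein.  The
alternative `coding="essential"` additionally counts the promoter, RBS+spacer
and terminator of expressed genes.  CDS-only is the default; outputs record
which definition was used.

## Mutation operators

Seven per-type, per-bp rates (events·bp⁻¹·generation⁻¹) drive replication.
Event counts per replication are Binomial(L, rate), independent across types.
Within one replication, chromosomal rearrangements (duplication, large
deletion, translocation, inversion, in shuffled order) are applied before
local events (substitutions and InDels, in shuffled order); each event draws
its coordinates uniformly on the genome length current at the moment of
application.

* Coordinates are 0-based; a span (p1, p2) is the circular run of
  `((p2−p1) mod L)+1` positions starting at p1; insertions insert *before*
  the given position.
* InDel sizes are uniform on [1,6]; insertion payloads are i.i.d. uniform
  bits.  Duplication/large-deletion segment sizes are uniform on [1,L]
  (drawing both endpoints uniformly yields exactly that law).
* Deletions that would empty the genome (size ≥ L) are discarded and logged,
  keeping L ≥ 1 without biasing other types.  Whole-genome translocations are
  likewise discarded.
* Translocations excise the span, re-close the circle, then draw the
  reinsertion point on the shortened sequence; the segment is reinserted
  as-is or reverse-complemented (flag drawn uniformly — whether reinsertion
  can invert is not constrained by the model, so both behaviours sit behind
  the flag).
* With all seven rates equal there is no net insertion/deletion pressure; the
  residual half-bp asymmetry from rejecting size-L deletions is far below the
  sampling noise of any experiment here (verified by Monte Carlo at 3-SE
  tolerance).

Every applied event is logged with its drawn parameters; replaying a log
against the parent reproduces the child bit-exactly.  Lineage storage relies
on this: only parent pointers and event logs are kept per generation, and
ancestor genomes are reconstructed by replay.

## Population dynamics

Individuals sit on a toroidal W×H grid.  Each generation, every cell draws a
parent among its 9 toroidal neighbours (self included) with probability
proportional to raw fitness, and is refilled by a mutated replicate of that
parent.  Raw-fitness weighting composes with the exponential fitness so that
k acts as the selection-gradient knob.  Only mutated offspring are
re-decoded; unmutated children inherit the parent's genome object and cached
metrics.  On grids narrower than three cells, a neighbour reachable through
several toroidal offsets counts once per offset, which keeps the nine-draw
semantics defined at toy scale.

Randomness is counter-based: generation t of a run with seed s consumes a
Philox stream keyed (s, t), with draws consumed in fixed cell order.  A run
can therefore be restarted from any genome snapshot bit-exactly, and the same
(config, seed) always reproduces every output byte.  Individual replications
are replayed from event logs rather than from per-cell streams.

## Experimental protocol

**Wild types.**  A WT is evolved from a random founder under basal conditions
(N₀ individuals, rate μ₀ per type, no bias).  Random founders are resampled
until they decode to at least one protein *and* beat the empty phenotype by
at least 10⁻³ of metabolic error; a genome with no expressed gene feels no
selection gradient, and below that margin early dynamics degenerate into
neutral drift of genome size (transient ballooning or collapse).  This
mirrors the seeded-founder practice of established platforms of this kind.
After the run, the line of descent of a random final cell is reconstructed,
truncated ΔG generations before the end (with a coalescence check on two
random final cells; a warning is raised if they have not coalesced), and the
ancestor at the horizon is the WT.  A stationarity indicator — the linear
slope of genome length over the last 20% of the analyzed lineage — is
reported.

**Perturbations.**  A clonal population of N copies of a WT evolves under new
(N, μ, bias) conditions.  The line of descent of a random final individual is
truncated at G_total − ΔG; per-generation fitness, total/coding/noncoding
size and coding fraction are reported along it, with replicative robustness
estimated at a fixed cadence.

**Condition matrix.**  The 13 (N, μ) combinations span multipliers
{1/16, 1/4, 1/2, 1, 2, 4, 16} arranged so the product N×μ falls in the
classes {1/16, 1/4, 1, 4, 16, 256}×N₀μ₀ with {1, 1, 4, 3, 3, 1} members.
Population sizes snap to the nearest perfect square (e.g. N₀/2 → 529 = 23²,
2N₀ → 2025 = 45²) because the population lives on a square-most grid.

**Mutational biases.**  Four configurations impose a 2:1 ratio within one
pair of opposing types (large deletions vs duplications, small deletions vs
small insertions, and their mirror images), rescaling the pair to 4/3·μ and
2/3·μ so the pair sum — and the total rate — is conserved.

**Scales.**  Desk-scale defaults are N₀=256, L₀=2,000 bp, μ₀=1e-5 per type,
50,000 WT generations, 20,000 perturbation generations, ΔG=1,000, 5
replicates.  μ₀=1e-5 keeps the per-genome event rate 7·L₀·μ₀ ≈ 0.14 in the
same regime as the full-scale design (7·14,000·1e-6 ≈ 0.10), which is what
the robustness mechanism cares about.  `ExperimentConfig.paper_scale()`
restores the full design (N₀=1,024, μ₀=1e-6, 10M WT generations, 2.1M
perturbation generations, ΔG=100,000, 10 replicates, 5 WTs, 10,000
robustness offspring); those runs are cluster-sized.

## Replicative robustness

`estimate_robustness` draws R offspring (R=10,000 at full scale, 1,000 desk
default; always reported with a Wilson 95% CI so R is auditable) and counts
those with bit-identical metabolic error.  Offspring that drew no event are
neutral without re-decoding.  Per-type decompositions use *forced single
events* — R offspring each carrying exactly one event of one type — rather
than post-hoc classification, which would confound the decomposition; the
semantics is recorded in the output.  Exhaustive single-event oracles
(substitutions up to L=64; other types up to L=32, where the full event space
is enumerable) validate the Monte-Carlo estimators, composed through the
closed form ν = (1 − μ(1 − ν₁))^L for Binomial event counts.

Under the independent-events model, deleterious events are a Poisson stream
of rate −ln ν; multiplying all rates by c predicts ν(c·μ) = ν(μ)^c.  This is
the analytic core of the rate-scaling analysis: a 92% robustness at base
rates predicts 71.6% at 4× and 26.3% at 16×.

## Synthetic fixtures

Planted genomes give every decoder stage analytic ground truth: gene
cassettes (promoter with a chosen number of planted mismatches, RBS, spacer,
START, codon string, STOP, terminator) are embedded in filler guaranteed free
of promoters, terminators and gene-start motifs on both strands.  Because a
terminator pattern occurs in 1/16 of random positions, filler cannot be
rejection-sampled as a block; it is grown incrementally, checking every motif
window a new bit completes (the terminator predicate is strand-symmetric, so
one strand suffices), with bounded backtracking and an all-zero fallback
(itself motif-free).  Random codon strings are grown the same way, since
long codon runs almost surely fold into hairpins.  An assembly-level checker
then distinguishes *hard* violations (extra promoters, transcript-truncating
terminators, extra gene starts inside transcripts — these change decoding
and, if inside a cassette, make the spec unrealizable) from *soft* ones
(harmless motifs such as the hairpins the promoter consensus itself
contains), resampling filler blocks until the genome is clean.  Ground-truth
protein parameters come from an independent table-lookup Gray decoder.

Fixtures exist for correctness, not realism: they have no overlapping genes,
operons, or evolved codon statistics, so passing fixture tests validates the
decoding contract, not the statistical structure of evolved genomes (the
evolved-WT tests cover that side).

## Test-scale choices

The test suite runs the full protocol at a reduced scale chosen once:
N=64 control grid (4×N = 256), L₀=1,000 bp, μ=5e-5 per type, a
20,000-generation WT phase, and 3,000-generation perturbations with 5
replicates.  At this μ an evolved ~1.7-kb genome draws ≈0.6 events per
replication, the regime where robustness selection operates.  The test
environment uses a simplified target of two narrow Gaussians,
(0.35, 0.35, 0.035) and (0.65, 0.45, 0.04): a handful of triangle kernels
approximates it well, so the adaptive plateau is *reachable* at this
mutation supply.  That is essential, not cosmetic.  Wild types are defined
by structural stationarity, and the streamlining responses are properties of
the mutation–selection–drift equilibrium: if the WT still has large
adaptation headroom (as it does under the richer default target at any
desk-affordable run length), the adaptation flux dominates — larger
populations fix more beneficial duplications, dragging noncoding DNA along —
and masks the streamlining response entirely.  With the scaled-down target
the WT passes through gene discovery, expansion (to ≈3.8 kb) and
streamlining, and settles near 1.5–1.8 kb with a stable coding compartment
while fitness changes only marginally; perturbations then measure the
equilibrium shift, as in the full-scale design.

The directional claims (4×N prunes noncoding but not coding; 4×μ prunes
both) are assessed with one-sided Mann–Whitney tests at α=0.05 against the
control, on the final line-of-descent ancestor of each replicate.  Under the
elevated test-scale μ the 4×μ arm also reproduces the transient fitness cost
of robustness selection: its populations end fitter-genome-poorer — smaller
coding size and lower fitness — than the control, the signature of indirect
selection overriding direct selection.

## Numerical and degenerate-input choices

* Phenotype grid D=1,024; trapezoidal integration; no epsilon anywhere in
  neutrality comparisons (exactness is guaranteed by canonical evaluation
  order, not tolerances).
* Promoters are reported in strand-local coordinates (lagging-strand position
  s maps to stored position L−1−s); ordering is (position, strand).
* Genomes of length < 22 bp are still scanned circularly (windows wrap as
  often as needed); a 1-bp genome is valid and decodes to nothing.
* A zero-fitness 3×3 neighbourhood cannot occur (fitness = exp(−k·g) > 0) but
  selection falls back to a uniform draw if it ever did.
* Gray fractions are accumulated as descending powers of two, so genes of
  arbitrary length cannot overflow; for ≤52 codon bits the result is
  bit-identical to the integer-ratio definition.

## Known limitations

* No recombination, lateral transfer, transposable elements, or
  homology-dependent rearrangement rates; fitness depends only on the summed
  phenotype.
* Effective population size is not estimated; local competition makes Ne
  slightly exceed N, which shifts isoclines slightly.
* Desk- and test-scale runs reproduce directions and invariants, not the
  full-scale equilibrium values (genome sizes around 14 kb, coding fractions
  0.6–0.9), which require millions of generations at N up to 16,384.
* In-memory lineage records grow linearly with generations × mutated cells;
  multi-million-generation runs need the save/load path and periodic genome
  checkpoints rather than a single in-memory record.
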