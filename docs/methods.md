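# Methods

This note records the models, conventions and design choices behind each
component, what the synthetic data does and does not emulate, and the
numerical details a maintainer would need to modify the code safely.

Throughout, coordinates are 0-based half-open internally and converted at
file boundaries (coords tables and masker `.out` tables are 1-based
inclusive; BED is half-open; site tables gain 1-based positions on
write). All randomness flows through `numpy.random.default_rng`; child
seeds are derived with `SeedSequence.spawn` and kept below 2^31, so a
fixed top-level seed yields byte-identical outputs.

## Synthetic genomes and planted features (`simgen`)

Genomes are iid base sequences at a chosen GC fraction — no
isochores, no codon structure, no pre-existing repeats. This is
deliberate: every analysis here is driven by exact sequence matching or
interval arithmetic, and an iid background gives analytic control over
false-positive rates (e.g. the chance that a random 20-mer recurs in a
2-Mb genome is ≪ 1).

Divergence is substitution-only: each site mutates independently with the
stated probability, to one of the three alternative bases uniformly. The
observed Hamming fraction is therefore binomial with mean exactly equal
to the parameter, which is what makes divergence landscapes and identity
assertions in the tests exact. No indels are modelled; alignment-gap
robustness is exercised only through the edit-distance machinery, not
through the generator. Back-substitution is not modelled either, which
is immaterial at the ≤ 0.4 divergence ceiling enforced.

Repeat planting inserts sequence (the genome grows; nothing is
overwritten), sampling insertion points uniformly per contig with
rejection of points inside previously planted features. After every
insertion the truth ledger's coordinates are shifted consistently, so the
ledger always names each feature in final coordinates; a planted
interval can be re-extracted and compared to what was planted. Tandem
arrays are head-to-tail monomer repeats truncated to the drawn array
length, then mutated as a unit.

Inversions reverse-complement an interval in place. An optional flank
element plants one mutated element copy immediately at each junction
(two per inversion) — the construction used to validate the enrichment
test. Repeats fully inside an inverted interval have their ledger
coordinates mirrored.

Reads are single-end, fixed-length, uniform-start. Sex is a dose model:
male contigs all at dose 1; female at dose 1 for autosomes, 2 for X, 0
for Y, applied as sampling weight (the X is not duplicated as sequence).
Real libraries are paired-end with non-uniform coverage and sequencing
error profiles; none of that matters for coverage-ratio or k-mer
exclusion logic, which is all that consumes these reads. Two artefacts of
the uniform-start model are worth knowing: contig *edges* are
undercovered (read starts cannot precede position 0), so a handful of
terminal k-mers of an autosomal contig can be absent from a finite female
read set; and expected depth is exact rather than Poisson-dispersed
across the whole contig.

Genotype panels are haploid: each sample's allele at each site is an iid
Bernoulli(p) draw with p solving 2p(1−p) = π_target, so expected
per-site heterozygosity equals the target exactly — no frequency
spectrum, no linkage, no population structure. Missingness is iid per
genotype. This suffices to test the estimator's denominator logic and
its unbiasedness, not its behaviour under realistic demography.

What passing tests on this generator show: the *computations* are
correct — bookkeeping, filters, statistics and decision rules do what
they claim on data whose truth is known. What they do not show: robustness
to assembly errors, indel-rich alignments, non-uniform coverage, or
repeat families with internal structure beyond what is planted.

## Anchor alignment (`alignio`)

The internal aligner finds canonical k-mers (lexicographic minimum of a
window and its reverse complement; k odd elsewhere, k = 20 here where
both orientations are tracked explicitly) that occur exactly once in each
genome, takes the intersection as anchors, and chains ref-sorted anchors
of consistent orientation whenever consecutive anchors are within
`chain_gap` (default 5 kb) on both sequences and the query progresses
monotonically (ascending for `+`, descending for `−`). Segment identity
is the fraction of the reference span covered by the union of anchor
windows — a lower bound on true identity, adequate because the standard
filter sits at 90 % and synthetic divergence in rearrangement tests is
≤ 5 %. Chains overlapping on the reference by more than half their span
are resolved in favour of the longer chain, deterministically by
(span, start). `anchor_k` below 12 is rejected outright: in genomes of
the scale handled here shorter seeds recur by chance.

The segment filter is two-stage, mirroring its usual usage: first drop
raw matches < 100 bp, then drop segments below 90 % identity or spanning
< 1 kb in *either* genome. Both stages are per-row; whether identity and
span should be assessed before or after any per-chromosome merging is
genuinely open, and per-row is the declared choice.

## Orientation blocks and breakpoints (`rearrange`)

Blocks are maximal runs of same-strand, query-monotone, gap-bounded
segments (`max_intra_gap` default 50 kb — large enough to bridge
repeat-induced alignment gaps, well below inversion sizes). A strand flip
between adjacent blocks yields a breakpoint interval
`[left.ref_end, right.ref_start]`, collapsing to a width-0 point when
blocks abut. A monotonicity break *without* a strand flip splits the run
(a translocation signature) but produces no inversion breakpoint.

Nested inversions need no special recursion: an interval re-inverted
inside a larger inversion alternates strand again in reference
coordinates, so its boundaries appear as ordinary block transitions. This
is a deliberate simplification of the design space; one consequence is
that the query-side ordering of nested blocks is not further interpreted.

`junction_guard` handles a subtle ambiguity: if the sequence at a
junction happens to read identically in both orientations (chance
micro-homology), an exact-match anchor can legitimately extend past the
physical breakpoint, and the inter-block gap then excludes the true
coordinate by a few bases. Since micro-homology longer than k occurs with
probability ~4^−k, a guard of one anchor length per side makes the
interval a true confidence interval for the junction; anchor-based
pipelines pass `junction_guard=anchor_k`. Reported resolution includes
the guard.

Sharing classification clusters inversions across strains by union-find,
matching two inversions when both boundaries agree within `match_tol`
(default 1 kb); a cluster observed in every strain is fixed, otherwise
polymorphic.

## Y-contig classification (`sexlink`)

K-mers are canonical 15-mers (k must be odd — an even k can equal its own
reverse complement, making canonicalization ambiguous); windows covering
an ambiguous base or a base under the Phred cutoff (default 5) are
excluded. "Single-copy" means exactly one occurrence across the *whole
assembly*, not per contig — the stricter, assembly-wide reading.
Membership structures are sorted uint64 arrays; read sets are processed
in bounded-size chunks so memory stays flat at any depth.

The decision rule is declared, not derived: Y requires female/male ratio
≤ 0.3 AND ≥ 50 % of single-copy k-mers unmatched by female reads AND
≥ 25 % single-copy k-mers (a contig made of repeats has too few
single-copy k-mers for the exclusion signal to mean anything); X requires
ratio ≥ 1.5 with unmatched ≤ 25 %; A requires ratio within [0.7, 1.3];
anything else is ambiguous. All thresholds are parameters of a
`Thresholds` dataclass and are recorded in the output. Contigs with male
depth < 1× get an undefined-ratio flag rather than a noise quotient.

Coverage is consumed from per-contig mean-depth tables; for simulated
reads the depth is computed exactly from read provenance, which removes
the mapper from the validation loop entirely.

## Repeat statistics (`repeatscape`)

Genome proportions merge overlapping same-subclass annotations before
summing, so percentages per partition cannot exceed 100. Divergence
landscapes intentionally use the opposite policy — plain length sums per
1 % divergence bin (`floor(pct_div / bin_width)`) — because that is the
semantics of the standard masker-output parsers whose plots these
reproduce; column sums then equal total annotated bp per subclass
exactly, an invariant the tests enforce. The masker-reported divergence
is used as-is, with no Kimura correction. Window densities apportion each
annotation to windows by exact overlap, conserving mass per chromosome.
Tandem-array loci merge one family's hits within `merge_gap` (default
100 bp — no merge rule is canonical for ITR arrays; this value keeps
monomer-interrupted arrays whole without bridging distinct loci).

## Breakpoint enrichment (`bkpt_enrich`)

Extension is single-pass: a region grows to the outermost endpoints of
annotations *directly* overlapping it (no transitive chaining through
newly covered annotations). The test statistic is total target bp in the
extended regions, with target intervals merged first so overlapping
annotations are not double-counted. Null regions are size-matched to the
*pre-extension* breakpoints, drawn uniformly on the host chromosome
(conditioning out chromosome-scale density differences; `genome_wide=True`
removes the conditioning) and extended identically (`extend_null=False`
disables, for sensitivity analysis). The plus-one p-value
`(1 + #{null ≥ obs}) / (n_perm + 1)` never reaches zero and is exact
under exchangeability.

Two practical notes. First, interval logic is half-open, so an element
*abutting* a width-0 breakpoint point does not overlap it; a called
breakpoint interval always straddles its junction, and the validation
protocols therefore represent truth junction points as 2-bp straddling
intervals. Second, because extension converts any partial overlap into a
full-copy overlap, a target family of fixed copy length makes the
statistic a lattice of that length and the p-value conservative through
ties; the calibration protocol plants variable-length arrays so the
statistic is effectively continuous and the nominal α = 0.05 rate is
recovered.

## Repeat dynamics (`repeat_dynamics`)

All sequence comparison is edit distance (edlib), so gaps count as
differences; "≤ 20 % divergence" is operationalized as ≥ 80 % identity.
Clustering is greedy and deterministic: families sorted by length
descending (name as tie-break) join the first cluster whose *founder*
matches at the threshold over the shorter sequence (end-free alignment of
the shorter into the longer, both orientations). Search is exact 12-mer
seeding, diagonal-banded candidate windows, then end-free alignment of
the full consensus into the window; copies below roughly 80 % identity
can escape seeding, which is acceptable because every decision rule
operates at or above that bar. Own-genome abundance for the novelty test
comes from the annotation table (the masked copies), not from re-search,
and mean copy divergence is length-weighted.

Insertion-site probing: a locus's left and right 100-bp flanks are
concatenated into a 200-bp junction probe representing the *empty* site.
In another genome the site is `intact` only when exactly one continuous
hit covers the full probe at ≥ 90 % identity; a genome carrying the same
insertion splits the probe (edit distance inflated by the intervening
array) and scores `not_intact`; multiple qualifying hits (paralogous
flanks) score `ambiguous`, and ambiguity never supports a call. A
private insertion is called only when the site is intact in *every*
other genome. The host-gene annotation field is a reporting hook, left
null.

## Windowed diversity and divergence (`popgen_windows`)

Samples are haploid-equivalent (inbred strains contribute one allele;
diploid VCF genotypes contribute two). Windows are fixed, non-overlapping
and anchored at position 0. π sums per-site pairwise differences
`n_ref·n_alt` over per-site comparisons `C(n_called, 2)` — a ratio of
sums, not a mean of ratios — so invariant genotyped sites dilute π while
ungenotyped sites change nothing; both directions are property-tested.
Sites with fewer than two called alleles are skipped; windows with no
comparisons are NaN, never zero (reporting zero would silently convert
missing data into claimed invariance, the exact failure mode the
invariant-site-aware formulation exists to avoid). Dxy uses only sites
genotyped in both populations. Sites with more than two alleles are
excluded and tallied (`attrs['n_multiallelic']`), not estimated. Class
contrasts use the two-sided Mann-Whitney test with midranked ties and
the normal approximation with continuity correction for larger samples
(exact enumeration for small tie-free samples).

## Validation protocols and problem sizes (`protocols`)

The canonical experiments live in one module so the test suite and the
reproduction script share identical conditions:

* **Sexed coverage / Y classification**: a 5-Mb assembly (20 autosomal
  175-kb, 6 X 150-kb, 4 Y 150-kb contigs), 30× error-free male and female
  read sets at 150 bp. Large enough that per-contig depth concentrates
  tightly around its expectation and every contig carries tens of
  thousands of single-copy k-mers; small enough to run in about a minute.
* **Breakpoints**: a 2-Mb chromosome, five non-overlapping 50–300-kb
  inversions at least 10 kb apart (so inter-inversion blocks survive the
  1-kb span filter), 1 % background divergence, k = 20 anchors. At 1 %
  divergence about 82 % of 20-mers are intact, so anchor gaps near
  junctions are a few bases and called intervals are two orders of
  magnitude inside the 1-kb resolution target.
* **Permutation calibration**: 200 replicate 400-kb genomes with ~200
  uniformly planted variable-length (100–500 bp) target arrays and ten
  500-bp regions drawn exactly as the null draws them; the α = 0.05
  rejection rate over replicates estimates the test's size. The
  enrichment construction (target only at inversion junctions) must give
  the minimal attainable p = 1/(n_perm+1) in every replicate.
* **π recovery**: 10 haploids × 200-kb sites at π_target = 0.01 with 10 %
  missingness; the genome-wide estimate is checked within three binomial
  standard errors, a conservative band since the estimator's per-site
  variance is below binomial at this allele-frequency regime.
* **Repeat-dynamics trios**: 20 replicate trios built from a common
  200-kb ancestor carrying shared families and shared ITR arrays; genome
  A additionally carries a qualifying unique family (6 kb at 1–6 %
  divergence), a sub-threshold decoy singleton (0.9 kb), and one private
  1.5-kb ITR array placed at an isolated, fully flanked locus. Novelty
  verdicts and insertion calls are scored for exact precision and recall.

## Known limitations

* No indel model in the generator, so alignment-gap handling is exercised
  only by the edit-distance components, not end to end.
* The anchor aligner assumes high homology and unique k-mers; it is a
  validation instrument for synthetic pairs, not a replacement for a
  whole-genome aligner on real assemblies.
* Seed-based search misses homology below ~80 % identity by design.
* The Y/X/A decision thresholds are declared defaults, not fitted to any
  dataset; real analyses should inspect the profile scatter before
  trusting them.
* Chromosome-fusion detection, de novo repeat-family discovery, read
  mapping and variant calling are out of scope; the pipeline consumes
  their standard outputs.
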