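# Methods

## The problem and the model

ChIP-tiling-array experiments measure protein–DNA binding as hybridization
intensities of immunoprecipitated chromatin on probes tiled across the
genome (here 25-mers every 36 bp, three biological replicates per
condition). Binding appears as locally elevated specific-IP/control-IP
ratios spanning many adjacent probes; noise appears as heavy-tailed,
probe-correlated intensity variation shared between conditions. The
pipeline's job is to turn the replicate intensity matrices into a ranked,
FDR-calibrated set of bound regions and the downstream statistics a
binding study reports: target-gene lists, peak-multiplicity gene classes,
overlap and repression-bias significance, and consensus-motif enrichment.

## Signal model and normalization

Background intensity for probe *p* in replicate *r* is modelled (and
simulated) as `exp(mu + a_p + e_pr)` with a per-probe affinity `a_p ~
N(0, 0.5²)` shared across replicates *and* conditions — the same probe
sequence hybridizes the same way in both IPs — plus replicate noise
`e_pr ~ N(0, 0.3²)`. Binding multiplies the background by
`1 + (fold − 1)·K(x)` where `K` is a triangular kernel falling linearly to
zero at ± half-width (default 500 bp), an adequate approximation of the
pileup of sonicated fragments; a Gaussian kernel is selectable.

Normalization is median scaling of every replicate to the grand median
followed by quantile normalization applied jointly to all specific and
control replicates, so both conditions end on a common intensity
distribution. The enrichment score is `log2(mean_specific /
mean_control)` per probe, smoothed by a sliding trimmed mean: a bp-defined
window `[p − w//2, p + (w − w//2))` with `w = 675` bp, removing
`floor(trim · n)` values from each tail with `trim = 0.1` per tail. The
trim fraction and the bp-versus-probe-count window definition are not
canonical across tiling-array tools, so both are configuration, not
constants. Windows always contain the probe itself, making smoothing
well-defined at any probe density. `.sgr` files are written 1-based for
genome-browser compatibility; everything internal is 0-based half-open.

## Peak calling and the empirical FDR

Candidates are maximal runs of probes with smoothed score ≥ threshold
(default 0.8 log2 units); runs separated by at most `2 × spacing` bp are
merged, so one missing probe does not split a peak while distinct peaks do
not fuse. The summit is the leftmost maximal probe (deterministic
tie-break); the region extends from the first to last probe of the run
plus one probe spacing.

The null ensemble swaps balanced subsets of replicate labels between the
specific and control panels (for 3 vs 3 there are 19 distinct non-identity
swaps) and reruns ratio → smoothing → candidate scan per iteration
(default 20). Label swapping preserves the shared probe-affinity structure
that makes naive permutation nulls anticonservative. With fewer than two
replicates per condition the fallback is within-chromosome permutation of
raw scores; the manifest records which construction produced a run. For a
peak height *h*, `FDR(h) = mean per-iteration count of null peaks ≥ h /
observed count of peaks ≥ h`, scanned over the observed heights exactly
(no binning), clipped at 1, and made non-increasing in *h* by a running
minimum so a stricter cutoff never reports a worse rate. A region gets the
most stringent tier of {1, 5, 10, 25} % whose height threshold it meets;
the tier sets are therefore nested by construction. This estimator is a
peak-level reconstruction of tiling-array FDR practice, chosen as the
simplest estimator consistent with tiered region lists; it does not claim
numeric equivalence with any specific historical implementation.

## Gene assignment and peak classes

A region maps to every gene it overlaps by ≥ 1 bp (many-to-many, strand
ignored); a region overlapping nothing maps to the single gene minimizing
the distance from the region centre to the nearer gene end, ties broken by
smaller gene start then lexicographic id. No maximum distance is applied
to nearest-gene assignment. An optional blacklist (e.g. tandem histone
repeat genes) removes genes *after* assignment, so a region near a
blacklisted gene is not silently reassigned. Peak classes use the nested
tiers: *single* = exactly one 10 % peak and no further 25 % peak;
*multiple* = ≥ 4 peaks at 10 %; otherwise *unassigned*.

## Resampling statistics

All Monte-Carlo tests report `p = (b + 1)/(n + 1)` where *b* counts null
iterations at least as extreme as observed — strictly positive, with a
floor of 1/10,001 at the conventional 10,000 iterations. The overlap test
redraws *both* gene sets each iteration (statistically equivalent to
fixing one, kept literal for fidelity); the label-bias test draws the
without-replacement labelled count directly from the hypergeometric
distribution, which is exactly the sampling scheme, and is cross-checked
in the tests against scipy's exact hypergeometric tail. Term enrichment
uses two one-sided binomial tails per term with Bonferroni correction
over tested terms (corrected p < 0.05 significant). The co-occurrence
test keeps set A fixed and relocates each B region uniformly within its
own chromosome, preserving lengths — the standard conditional null and
the cheapest defensible one.

## Motif enrichment

Sequences of exactly 400 nt are extracted around peak summits (edge-
clipped windows are dropped with a warning, never padded). IUPAC
consensus scanning tests every position on both strands, counts
overlapping matches, and counts a position once when the forward and
reverse-complement patterns coincide (strand-symmetric motifs). N never
matches. Enrichment compares the total count over peak sequences with the
counts in background sets matched in set size and sequence length, drawn
uniformly from the genome (chromosomes weighted by eligible length,
random strand, N-containing draws resampled):
`z = (observed − mean_bg)/sd_bg` (unbiased sd), significant when z > 3.
The expected per-bp match rate of a consensus is the product over
positions of the allowed-base probabilities, summed over the two strand
patterns minus their per-position intersection; for TAAT under uniform
composition this gives 2·(1/4)⁴ = 1/128, i.e. one expected site per
128 bp — the double-stranded reading is the one that makes that spacing
come out, and is the convention used throughout.

## What the simulator emulates — and what it does not

The generator produces: multi-chromosome random sequence with configurable
base composition; non-overlapping genes with log-normal lengths (mean
5.6 kb, matching a compact invertebrate genome) placed by stick-breaking;
accessibility domains cut at random insulator positions, with OFF states
assigned to a random domain subset whose total length best matches the
requested silenced fraction (keeping the silenced share stable across
seeds, which iid per-domain states do not); single planted peaks placed
inside randomly chosen genes and ≥ 4-peak clusters placed inside one long
gene each, separated by three half-widths so neighbouring peaks remain
resolvable after smoothing; and expression labels with controllable
P(down | bound) vs P(down | unbound) — defaults 0.76 vs 0.62, pooling to
roughly 65 % down — emulating a repression-biased regulator. In
constrained mode no planted region intersects an OFF domain, the
simulated counterpart of binding exclusion from Polycomb-silenced
chromatin.

Not emulated: probe cross-hybridization, GC-dependent affinity, replicate
batch effects, copy-number variation, or any empirical noise spectrum —
the noise model is a structural stand-in validated by calibration
properties (background-only conditions are statistically
indistinguishable; the label-swap null reproduces the observed background
peak-height distribution). Passing tests therefore demonstrate the
*machinery* is correct and calibrated on data with the assumed structure,
not that real arrays meet those assumptions.

## Numerical and scale choices

Default study size is a 1 Mb genome (600 + 400 kb), ~28,000 probes, 100
genes, 60 planted regions, 20 null iterations — the whole pipeline runs in
seconds while leaving every statistic comfortably powered; the validation
suite uses 300 kb–1 Mb genomes and 10–50 seeds for calibration checks.
Resampling defaults are 10,000 iterations for gene-set tests (the add-one
floor of ~1e-4 then matches study-scale reporting) and 1,000 for region
shuffling. Seeds fan out from one global integer through named
SeedSequence substreams, so stages are independently reproducible and
every artefact is byte-stable under a fixed config + seed (the manifest
hashes prove it). Degenerate inputs fail loudly: zero medians, mismatched
probe grids, empty annotations, zero background variance, regions longer
than their chromosome, infeasible placements (with the unplaced features
listed).

## Known limitations

The FDR estimator is peak-level; probe-level FDR variants would give
different counts at the same nominal tier. Balanced label swaps mix
signal into the null's "control" side, slightly inflating null peak
heights and making the tiers conservative when signal is dense. Nearest-
gene assignment is uncapped and annotation-naive (no promoter weighting,
no regulatory-domain model). De-novo motif discovery is out of scope —
the motif module covers consensus scanning and enrichment only.
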