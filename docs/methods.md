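# Methods

## Problem setting

The package detects and quantifies the *hgcAB* mercury-methylation gene
pair in a gene catalog predicted from a metagenome co-assembly of
brackish water-column samples. Inputs are an amino-acid catalog joined to
gene coordinates on contigs, a per-sample gene read-count matrix with
per-sample totals of annotated reads, and a sample manifest carrying
station, date, depth, oxygen and filtration descriptors. Assembly, gene
prediction and read mapping are upstream of this package and out of
scope; the catalog and counts are taken as given.

## Detection model

**Screening.** Candidates are produced either from an external
`hmmsearch` per-domain table (rows kept at full-sequence E-value ≤ 10⁻³,
boundary inclusive — the E-value semantics belong to the external search)
or from an internal position-specific log-odds profile. The internal
profile is built from a reference alignment: columns with more than 50 %
gaps are dropped, residue probabilities are Laplace-smoothed with
α = 0.1 pseudocounts per residue, and scores are log₂(p/background) in
bits against a uniform background of 0.05. A gene is scored by the best
ungapped placement of the profile along its sequence (partial overlaps at
either end are scored over the overlapping columns, which keeps
edge-truncated ORFs detectable) and kept when score / profile-length ≥
0.5 bits per column. This is deliberately not a full profile HMM with
insert/delete states: the screen only needs to separate hgc-like
sequences from unrelated background at catalog scale, because the motif
check decides. On the bundled synthetic material the margin is wide —
true and decoy sequences score ≈ 3 bits/column, random-composition
background scores negative — so the default threshold is not delicate.
Ambiguous residues (X) score zero in the screen and match no motif
position in verification (conservative: an X inside the motif window
cannot verify a candidate).

**Verification.** A candidate is verified iff its sequence contains at
least one window matching the degenerate motif of its target —
`NVWCA(A/G/S)GK` (hgcA cap-helix) or `C(M/I)EC(G/S)(A/G)C` (hgcB
ferredoxin). The leftmost match is recorded for determinism. Motif
patterns are configuration, not hard-coded, so additional accepted
variants can be supplied.

**Locus calling.** Verified hgcA and hgcB genes on the same contig are
paired when their gene ranks differ by ≤ 1, their intergenic distance is
≤ 500 bp, and (by default) they share a strand; "side-by-side" is not
quantified in the literature the workflow follows, so these defaults are
exposed. Pairing is greedy by ascending intergenic distance with each
gene used once, which deterministically resolves an hgcA flanked by two
hgcB candidates in favour of the closer one (operon-like geometry).
Unpaired hgcA become lone-hgcA loci carrying an edge-truncation flag
(from explicit partial annotations or coincidence with a contig
boundary); unpaired hgcB become lone-hgcB loci flagged central when not
at an extremity. The hgcB orientation relative to hgcA is recorded but
not used as a pairing filter. Loci are named ordinally — paired clusters
first, then lone hgcA, then lone hgcB, each block sorted by contig and
start — mirroring the cluster-first numbering convention of published
marker surveys. A relaxed profile hit without a motif near a lone hgcB
does not block the lone call.

## Abundance statistic

Per sample, relative abundance is
`100 × Σ reads(locus member genes) / total annotated reads`, reported in
percent and displayed in 1×10⁻³ % units. No gene-length normalization is
applied by default, reproducing the statistic exactly as surveys report
it; a reads-per-kilobase mode exists for sensitivity analysis only (it
changes the units and is off by default). "Total annotated reads" is
treated as a given per-sample denominator column; its upstream definition
is not interpreted here.

Redox zones are a total function of the manifest: normoxic when O₂ is
detected and ≥ 2.0 mL L⁻¹ (inclusive boundary), hypoxic when detected
below 2.0, anoxic when undetected. "No detectable O₂" is an explicit
boolean column, never inferred from a 0.0 reading, because detection
limits differ between instruments. Zone summaries report n, mean, sample
standard deviation (n−1 denominator; the convention is not stated where
such tables are published, so it is fixed here), min and max, plus an
all-water row; a single-sample zone reports sd 0 with a degenerate-n
flag.

Particle enrichment matches each 3 µm no-prefilter sample to the
0.2 µm-with-3 µm-prefilter sample sharing (station, date, depth) exactly
(fuzzy depth matching is available but off by default) and reports the
particle/free-living abundance ratio; a zero denominator is flagged
undefined rather than infinite.

Rarefaction subsamples the count vector without replacement
(multivariate hypergeometric over the hgc gene counts plus one bucket for
all other annotated reads) and counts hgc genes with ≥ 1 read, averaged
over replicates; raw reads are unavailable at this layer and the
expectation is identical. The closed form
E = Σ_g 1 − C(N−k_g, d)/C(N, d) is provided alongside and is what the
tests check against.

## Taxonomic placement

Queries are compared to a labeled reference set of hgcA / hgcB /
concatenated-hgcAB amino-acid sequences: pairwise global alignment
(BLOSUM62; gap open 10, extend 1), p = mismatches / aligned non-gap
columns, Poisson-corrected distance d = −ln(1 − p) capped at 5 (the cap
corresponds to p ≥ 1 − e⁻⁵ ≈ 0.993). Paired clusters are placed in
concatenated mode, lone hgcA in hgcA mode, lone hgcB in hgcB mode,
mirroring the separate trees marker surveys build for each pool.

The tree is standard neighbor joining on
Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with two deterministic
refinements: ties in Q are broken lexicographically on the smallest leaf
label under each candidate pair, and a negative branch-length estimate is
clamped to zero with the deficit moved to its sibling (additive inputs
never trigger clamping). NJ with Poisson distances replaces the
MUSCLE + approximate-ML (JTT+CAT) route used by the original workflow:
it is self-contained, has closed-form testable behaviour on additive
matrices, and suffices for nearest-reference placement at desk scale; an
externally computed Newick tree can be ingested for ML-based workflows.
Bootstrap support, when requested, resamples the columns of a supplied
alignment, rebuilds distances and trees, and reports per-edge split
frequencies under a fixed seed.

Assignment: the nearest reference minimizes patristic distance (ties
lexicographic). The consensus clade is read off the unrooted tree — every
edge splits the leaves in two, the query-containing side is a candidate
clade, and the smallest candidate with ≥ 2 references is used; exact
size ties (a query equidistant between groups) are resolved by taking
the union of the tied clades, which can only reduce resolution. The
lineage is the deepest rank prefix on which ≥ 75 % of clade references
agree; an empty prefix is reported "unidentified". A query at
(numerically) zero distance from a reference inherits that reference's
full lineage. The `-like` caution flag is raised when the query's
terminal branch exceeds the 95th percentile of reference terminal branch
lengths, operationalizing the qualitative "very long branch" caveat used
when such genes are labeled e.g. "Spirochaetes-like"; the quantile is
configurable. No attempt is made to reproduce figure-style clade
collapsing ("dominant monophyletic phylum when possible"), which is a
visualization rule, not an assignment rule.

## Synthetic data: what it emulates and what it does not

`build_figure2_fixture` deterministically reproduces the published locus
arrangement of the emulated 81-metagenome Baltic survey: nine contigs
with an adjacent same-strand hgcA+hgcB pair (two pairs carrying
NVWCASGK+CIECGAC, one NVWCAAGK+CIECGAC, six the common
NVWCAAGK+CMECGAC), thirteen contigs with a lone hgcA truncated at a
contig edge (alternating 5′/3′), three contigs with a lone central hgcB,
≥ 100 profile-similar decoys whose invariant motif cysteine is broken
(they must pass the screen and fail verification), and ≥ 100
random-composition background genes. All sequence material derives from
seeded synthetic consensus sequences (hgcA 280 aa, motif at position 91;
hgcB 96 aa, motif at position 31) — no database records are copied.
Mutation noise never touches the motif window of a true positive, so
ground truth is exactly the motif test.

`simulate_survey` layers counts and metadata on top. Defaults are the
emulated study's conditions: 65/9/7 samples in
normoxic/hypoxic/anoxic zones; expected summed hgc abundance 0.05, 1.0
and 2.1 ×10⁻³ % per zone (the published zone means, with "<0.1" read as
0.05); 12.9 million annotated reads per sample (the published mean
depth); negative-binomial per-gene counts (size 2.0 — metagenomic
overdispersion rather than Poisson) with per-sample mean chosen so the
expected summed abundance equals the zone effect; a 5-fold particle
enrichment on 3 µm samples, between the published 3× and 14× pair
ratios; and three matched filter-fraction pairs, added as anoxic
station/date/depth-sharing sample pairs (`n_fraction_pairs`), mirroring
the deep-station pairs of the emulated design. O₂ values are drawn
uniformly within each zone's definition. The companion
`build_survey_manifest` reproduces the survey's exact 81-sample
three-dataset structure (14 redoxcline + 30 transect + 37 time-series
samples; zone totals 65/9/7) with representative per-sample depths and
O₂ values, since the published description fixes the structure but not
per-sample numbers.

The generator does not simulate reads, assembly artifacts, chimeras,
fused hgcAB single-ORF architectures, compositional biases, or taxon
mixtures — so passing tests demonstrate correctness of the pipeline's
logic and statistics under its stated model, not robustness to real
assembly noise. In particular the screen's decoy/true separation is
easier than on real catalogs, which is why the external hmmsearch route
exists.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive (GFF3 convention) everywhere.
- Contig lengths come from an explicit lengths table or GFF3
  sequence-region pragmas; when absent they are inferred as the maximal
  gene end, in which case edge-truncation detection relies on explicit
  partial annotations.
- Profile invariant: per column, Σ_r 2^score(r) · background(r) = 1
  (within 1e-9), i.e. scores are exactly log-odds of a probability
  distribution.
- A pair with zero aligned columns gets the distance cap with a warning.
- Empty catalogs, empty locus lists and zero-sample zones degrade to
  empty outputs with warnings, not errors; invariant violations in the
  inputs (counts exceeding totals, duplicate ids, coordinates beyond
  contig ends) are hard errors naming the offenders.
- All stochastic stages (survey simulation, rarefaction, bootstrap) take
  explicit seeds; equal seeds give byte-identical outputs.

## Problem sizes used in the test suite

The suite exercises the pipeline at the generator's catalog scale
(~340 genes, 195 contigs) and summary statistics over 100 seeded survey
replicates for the zone-ordering check, 50 matched pairs for enrichment
recovery, 200 seeded trials for family-rank recovery against a 20-entry
reference fixture, and 1000 random sequences for the motif-scan oracle —
sizes chosen so each property is measured with comfortable statistical
margin while the whole suite stays desk-scale.

## Known limitations

- The internal screen is not a profile HMM and reports bit scores, not
  E-values; catalogs screened externally should use the domain-table
  route for published-threshold fidelity.
- NJ placement ignores rate heterogeneity across sites; long-branch
  queries are flagged rather than modelled.
- Fraction-enrichment pairing requires exact key matches by default;
  surveys with jittered depths need the fuzzy option.
- The abundance statistic inherits whatever biases the upstream
  "total annotated reads" denominator carries.
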