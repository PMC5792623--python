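# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions.  Coordinates are 0-based half-open everywhere
internally; 1-based only at formatted output boundaries (SAM POS).

## Synthetic data (`synthgen`)

**Genomes and insertions.** Reference chromosomes are i.i.d. base draws at
a configurable GC fraction (default 0.36, *Arabidopsis*-like).  A planted
insertion writes `left flank + element + TSD + right flank`, where the TSD
is the `tsd_length` bases immediately 5′ of the insertion point — the
source genome already ends in those bases, so the derived genome carries
the duplication flanking the element, as integration does.  The element
may be 5′-truncated and/or inverted (reverse-complemented after
truncation), mirroring a truncated, inverted LINE1 copy.

**Reads.** Inner-facing pairs from uniformly sampled fragments with
normal insert sizes (default 500 ± 50, 150 bp reads) and i.i.d.
substitution errors.  No quality modelling, PCR duplicates, or indels —
the detection method under study is pair-based and those features would
only add an aligner-calibration layer the package does not model.

**Bisulfite calls.** Cytosine contexts (CG / CHG / CHH, H ∈ {A,C,T}) are
read from each cytosine's own strand; cytosines lacking two downstream
bases at a chromosome end are skipped (community convention).  Region
states set context means — defaults 0.85 / 0.65 / 0.10 for a methylated
heterochromatic TE and 0.02 everywhere for unmethylated; these are
plausible placeholders chosen to mimic heterochromatic TE methylation, not
measured values.  Per-cytosine levels are Beta-distributed around the mean
with overdispersion 0.1 (purely binomial counts would be unrealistically
tight); depths are Poisson (default 30); `conversion_error` is the
probability that an unmethylated cytosine reads methylated.

**Crosses.** One chromosome carries the markers and the epiallele locus at
genetic (cM) positions; crossovers follow Haldane's map function (no
interference) — the simplest stated-assumption model.  The epiallele's
methylation state travels in cis, unchanged through meiosis, except that a
*ddm1*-homozygous-mutant parent loses each transmitted methylated allele
with probability ε per meiosis, irreversibly (default ε = 0.2,
configurable; no measured rate exists, so the default is only meant to
make loss visible within a few generations).  The *ddm1* locus is
unlinked.  F2 = selfed F1; F3 = one selfed offspring per F2 plant.

**Star evolution.** Tips evolve independently from one ancestor under the
TN93 rate matrix scaled to 1 substitution/site per unit branch length,
with branch length `rate × age`.  Defaults: π = (0.32, 0.18, 0.18, 0.32)
(AT-rich), transition/transversion rate ratio 2.  The ancestor is drawn
from the stationary distribution unless supplied, and is retained on the
result as ground truth.

**Accession/climate tables.** Groups (methylated / unmethylated /
deletion) default to the 21 : 39 : 77 proportions of a 137-accession
panel.  Methylation is exactly 0 for the deletion group (the element is
absent).  PPH expression is lower and post-dark chlorophyll higher in the
methylated group.  bio9 carries a planted monotone *decreasing* relation
with total methylation; the other 18 variables are independent nulls with
plausible European ranges.  LIG values equal present-day values minus a
2 °C warming applied only to non-methylated groups (their sites have
warmed since the last interglacial), which automatically makes the LIG
association weaker than the present one.  The default effect size
(8 °C ≈ 2 σ of the bio9 spread at full methylation) comes from a power
analysis: because ~¾ of accessions have methylation pinned at 0, rank
correlations are strongly compressed, and a 1 σ shift would leave the
planted signal near the detection threshold at n = 137; 2 σ yields
ρ ≈ −0.3…−0.45 and reliable detection at α = 0.05.

What the generators do **not** emulate: accession relatedness (no
demography/coalescent — the star phylogeny is exact by construction),
sequencing-quality artifacts, spatial autocorrelation of climate
variables, and trans-acting methylation modifiers.  Passing tests
demonstrate correctness of the algorithms under the stated models, not
robustness to the full messiness of real data.

## TE detection (`tedetect`)

`naive_map` is a deliberate stand-in for a production aligner on
(near-)error-free synthetic reads: exact k-mer anchoring (k = 31, leading
k-mer with trailing-k-mer fallback) plus full-string verification on both
strands; reads with several perfect placements are flagged non-unique and
excluded from anchoring.

Discordant pairs have exactly one mate on an element contig and the other
uniquely in the genome.  Genome-side anchors within
`insert_mean + 3·insert_sd` cluster together; + strand anchors lie left of
the breakpoint and − strand anchors right of it.  The breakpoint interval
is `[max(left anchor ends), min(right anchor starts)]`, an inclusive range
of candidate junction points; if deep coverage makes the sides overlap the
interval collapses to the midpoint base (deterministic tie-break).  With a
TSD the junction coordinate is intrinsically ambiguous within the
duplicated target site `[point − tsd, point]` — right-side reads carry the
duplicated bases and map that far left — so "contains the truth" means
intersecting that window.  Orientation is voted from the TE-side mate
strands (left anchor + TE mate on − ⇒ same orientation, and mirrored on
the right).  `min_support` defaults to 3 per side (no published
threshold exists); clusters below it are reported as candidates with a
reason, not calls.  Split (junction-spanning) reads are ignored — the
method is pair-based only; split-read refinement is a possible extension.

The TSD caller takes the reference flanks, the insertion-allele sequence
and the element *as inserted* (in practice obtained by sequencing the
carrier allele, as one would by PCR across the junction).  It returns the
longest s (≤ `max_tsd`, default 30) that immediately precedes and follows
the element while restoring the reference when one copy is removed — the
right-flank restoration check pins the length uniquely and resolves
coincidental extensions.  Equal-length ambiguities are broken toward the
copy adjacent to the breakpoint with the smallest start and flagged.

## Methylation statistics (`methstat`)

Levels are weighted (count-summed), not mean-of-cytosines: robust to
uneven depth, and the field's standard.  Zero covered cytosines yield an
*undefined* level (None), never 0.  The Fisher comparison pools reads
across the region's cytosines of a context into one 2×2 table (the
simplest faithful reading of a region-level exact test; a per-cytosine
variant would require multiplicity handling and is intentionally not the
default).  Chop-PCR models digestion as blocked by methylation of the
site's diagnostic cytosine; per-molecule survival multiplies across sites
and averages across alleles at equal dosage, so a heterozygote shows half
the uncut template and still a band (threshold 0.1 of input template).
Enzyme definitions carry per-enzyme context sensitivity (MspI is blocked
by outer-C/CHG methylation, HhaI by CG).  Accession classification
binarises at CG level ≥ 0.2 where only numeric levels exist (gel calls
are binary and need no threshold); an accession carrying *only* a
methylated 16.75 Mb copy has no category of its own in the five-way scheme
and is folded into NMR19-16u — a documented limitation (no such accession
occurs in the emulated design).

## Inheritance (`inherit`)

Pearson χ² without continuity correction (designs here have thousands of
plants; a Yates flag exists).  Mapping is recessive-selection by default,
mirroring the study design: select unmethylated-band plants, count
methylated-parent marker alleles among their 2n chromosomes as
recombinants, take the marker with the fewest recombinants as the point
estimate and the nearest flanking markers with strictly more recombinants
as the interval; ties widen the interval and are flagged, and a monotone
edge leaves that side unbounded (flagged).  A codominant counting mode
exists but is off by default.  Co-segregation summaries use Welch's
(unequal-variance) two-tailed *t* between the homozygous classes — the
safer choice when only "two-tailed t-test" is specified; single-plant
groups produce means without a test.

## Dating (`tedate`)

TN93 distances use the published closed form with the pair's empirical
base frequencies and pairwise deletion (sites with a gap/N in either
sequence excluded).  A non-positive log argument (saturation) raises a
flagged error; saturated pairs are excluded from means (an error only if
every pair saturates).  Equal frequencies and equal rates reduce the form
to Jukes–Cantor, which the tests verify to 1e-9 along with a numerical
model-inversion oracle.

Neighbor joining is standard Saitou–Nei; a negative branch-length estimate
is clamped to zero with the deficit moved to its sister branch, preserving
the pair's summed length (a common, documented convention).  The output is
the unrooted trifurcating tree in newick.

Rate calibration: `r = d_ortholog / (2 T_div)` with TN93-corrected
divergence by default (raw-proportion option available).  `T_div` defaults
to the midpoint (4.65 Myr) of the 3.5–5.8 Myr split-time interval, and the
endpoints are always reported as a sensitivity range — published estimates
do not say which value inside the interval to use.

The star estimate divides the mean pairwise distance by 2r.  The MRCA
estimate reconstructs the root sequence by marginal ML (pruning) under
TN93 with empirical frequencies and moment-estimated rate ratios, on the
NJ tree of the alignment (rooting at the NJ trifurcation; the model is
reversible so the root only selects the node being reconstructed), then
divides the mean *raw* tip-to-ancestor mismatch proportion by r —
"counting substitutions" rather than model-correcting them, with a
corrected mode available.  Per-site posterior ties break toward the higher
stationary frequency, then alphabetically; all-gap columns yield gaps.

Behaviour worth knowing: on data that truly follow a star phylogeny both
estimators are nearly unbiased and highly correlated (they count the same
mutations), with the MRCA estimate a few percent high because
reconstruction on a noisy NJ tree lets near-root tips imprint their
private mutations on the root.  The interval `[T⋆, T_mrca]` is therefore
*narrow* on star data, and its coverage of the truth is governed by the
common Monte-Carlo error, not by the interval width; the broad reported
uncertainty should come from the `T_div` sensitivity range, which
`date_insertion` always includes.  On real accession data, shared
post-insertion ancestry deflates pairwise distances and makes T⋆ a genuine
lower bound, which is why the two estimators straddle a wide range there.

Alignment construction is out of scope: inputs must be pre-aligned (a
utility strips all-gap columns).

## Climate association (`climassoc`)

Accessions group by the 4.45 Mb copy only: present + methylated,
present + unmethylated, absent (deletion — whatever the 16.75 Mb copy
does).  Spearman ρ is the Pearson correlation of average ranks after
pairwise deletion of missing values; p is exact (full permutation
enumeration) for n ≤ 10 and the t-approximation otherwise.  The rank-sum
test enumerates every group assignment exactly for combined n ≤ 20 (tie
averaging included) and uses the tie-corrected normal approximation above;
the paired signed-rank test serves present-vs-LIG comparisons within one
group (same accessions at two epochs), with all-zero differences flagged
degenerate (p = 1).  A variable counts as "associated" in an epoch when
its raw p against total methylation is < α = 0.05 — no multiple-testing
correction, matching how such scans are conventionally reported; a
Benjamini–Hochberg mode exists and is off by default, and the choice is
flagged in the report.

## Pipeline and formats

One YAML config drives all stages; every stochastic stage derives its seed
as `sha256(global_seed, stage_name)`, so stages are independently
re-runnable and whole runs are byte-identical (provenance headers carry
tool version, config hash and seed — never timestamps).  Unknown config
fields are rejected by name (exit code 2; runtime errors exit 1).
Formats: FASTA/FASTQ via Biopython; cytosine tables as TSV
(`chrom, pos, strand, context, count_methylated, count_total`, validated
with line numbers); a minimal SAM subset (QNAME, FLAG strand/mate bits,
RNAME, 1-based POS, MAPQ 0 = non-unique, match-only CIGAR); calls as
BED-like TSV; trees as newick.

## Test problem sizes

The suite exercises the statistical claims at deliberately chosen sizes:
F2 segregation at n = 10,000; dating recovery at 50 tips × 3 kb × 20
seeds; detection at 50 replicates of a 100 kb genome at 20–40×; mapping at
200 replicates of ~1,000 selected plants with markers every 2 cM; climate
null calibration at 500 replicates of 137 accessions.  These sizes give
the binomial/Monte-Carlo error bars the assertions rely on while keeping
the default test run fast.

## Known limitations

- The naive mapper assumes (near-)exact reads; it is not an aligner.
- TSD calling needs the inserted element's sequence (e.g. from junction
  PCR); inferring the element extent from reads alone is not attempted.
- Methylated-16-only accessions fold into NMR19-16u (see above).
- The climate generator plants a single-variable effect; correlated
  climate variables and population structure are not modelled.
- ε (ddm1 loss) and the synthetic methylation means are plausible
  defaults, not estimates.
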