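# Methods

## The measurement model

Bisulfite treatment deaminates unmethylated cytosine to uracil (sequenced
as T) while 5-methylcytosine resists conversion, so the methylation level
of a cytosine is estimated as the fraction of reads showing C rather than
T at that position. Two chemistry parameters bound the fidelity of that
readout: the **conversion efficiency** `c` (probability an unmethylated C
is read as T; default 0.995) and the **methylation protection** `m`
(probability a methylated C survives as C; default 0.995). The expected
raw percent methylation at a site with true methylation probability `p`
is therefore `100·(p·m + (1−p)(1−c))`, not `100·p` — the motivation for
control-anchored normalization below.

A non-directional sequencing library contains four strand classes: reads
from the converted original top (OT) and bottom (OB) strands and from
their PCR complements (CTOT, CTOB). In the plus-strand co-linear view,
OT/CTOT fragments report plus-strand cytosines as C (methylated) or T
(unmethylated), and OB/CTOB fragments report minus-strand cytosines at
plus-strand G positions as G (methylated) or A (unmethylated). A
consequence worth noting: at a fixed base coverage, the *call* coverage of
any one strand's cytosine is roughly half the base coverage, because only
two of the four classes can call it. At the default 500× base coverage the
per-site call coverage is ≈ 235×, giving a per-site binomial standard
error near 1.9 percentage points at p = 0.1.

## Alignment

The aligner is an exact in-memory k-mer (k = 20) seed-and-extend ungapped
aligner over the doubled circular genome, scoring candidates by
full-length mismatch count against the C→T and G→A collapsed references
(three seeds per read: start, middle, end). Only the unique best placement
— strictly fewer mismatches than any alternative across all four strand
classes — is kept; ties and misses are discarded and the ambiguity rate is
logged. Mates must align concordantly within the insert range (default up
to 700 bp). This is sufficient and fully verifiable at mitochondrial
scale; it does not handle indels, and indel-bearing data should be
aligned externally and imported via the cytosine-report reader.

PCR duplicates are removed by grouping fragments on (leftmost position,
fragment length, strand class) and keeping the first representative —
the coordinate convention of standard bisulfite deduplicators. Two
genuinely distinct molecules that happen to share all three keys are
indistinguishable from duplicates by construction; at 500× on 16.5 kb this
affects ~0.1% of fragments.

Positions covered by both mates of a fragment are counted **once** (the
molecule was measured once); methylation states are drawn per molecule in
the simulator precisely so that a double-counting implementation would be
caught by the oracle-equivalence tests.

## Full-potential normalization

Long-PCR products carry no methylation marks, so for each genotype the
untreated negative control measures the per-site conversion-failure
background `n_i` and the M.SssI-treated positive control the achievable
ceiling `x_i`. Sites covered by ≥ `min_reads` (default 10, inclusive) in
*every* control sample are validated; the per-site full potential is
`x_i − n_i` percentage points, and a sample's normalized level is

    normalized_i = clamp( (raw_i − n_i) / (x_i − n_i) × 100, 0, 100 ).

The baseline-subtracted form is the default because the negative control
estimates exactly the conversion-failure background; a plain ratio mode
(`raw / potential`) is available as a config switch for sensitivity
analysis. Sites with potential below `min_potential` (default 10 points)
are excluded to avoid dividing by an unreliable range at enzyme-resistant
sites; both thresholds are package defaults, not biological constants.

Two properties follow algebraically and are asserted exactly in the
tests: the positive control self-normalizes to 100 and the negative to 0
at every valid site, and normalized values are monotone in the raw level
at fixed potentials.

**A known bias of the scheme:** when the positive-control enzyme is
imperfect (per-site efficiency `e_i` with mean 0.9 in the simulator), the
normalized value estimates `p/e_i`, not `p`, so the genome-wide mean
normalized level sits near `E[p]·E[1/e] ≈ 11.1%` for a true 10% methylome
rather than exactly 10%. This is inherent to anchoring the ceiling at an
enzyme-limited control and is reproduced, not corrected, here.

## Statistics

Group comparisons operate per site on normalized percentages: one-way
ANOVA as the omnibus test and pairwise t-tests for tabulated contrasts.
Welch's t-test is the default (the equal-variance assumption is fragile
at n = 3); classical pooled-variance is a flag away. Sites with zero total
variance return p = 1 and are flagged degenerate. The joint significance
rule — p < α (default 0.05) **and** |mean difference| > 5 points — is
applied per contrast family: genotype contrasts use it, stage contrasts
conventionally do not (differences under 5 points are reported there), and
the rule is switchable per contrast. No multiple-testing correction is
applied by default, matching the source convention of testing ~800 sites
unadjusted; Benjamini–Hochberg is available and its use is logged
prominently. (One provenance note: the narrative of the source tables
refers once to site 14578 where the table itself prints 14,758; the table
is taken as canonical.)

qPCR quantification assumes a fixed amplification efficiency of 2.0
(perfect doubling; configurable per assay) since no standard curves are
modelled. The MeDIP 5mC/5hmC ratio is computed directly from the two
antibody Cts without input-fraction normalization (an input-subtraction
mode exists). ΔΔCT uses the arithmetic mean of the three reference-gene
Cts as the internal control; a geometric-mean-of-quantities alternative
differs only when reference efficiencies differ, which is outside this
model. Correlation pairs each expression replicate with its group's mean
site methylation and reports R², the two-sided correlation p value
(numerically identical to the regression F-test for a simple linear fit),
and the slope sign.

## The synthetic-data generator

The generator defines the study conditions the pipeline is validated
under: 150 bp paired-end reads, insert 300 ± 50 bp, 500× mean base
coverage, non-directional strand classes drawn uniformly, conversion
efficiency and protection 0.995, per-base sequencing error 0.001, 5% PCR
duplicates; true CpG methylation Beta-distributed with mean 0.10 and
concentration 20, non-CpG cytosines at 0.002; two overlapping ~8.3 kb
control amplicons jointly covering the circle, with positive-control
per-CpG enzyme efficiency Beta(mean 0.90, concentration 50); qPCR Ct noise
SD 0.15 with triplicates. Fragments of genomic samples may span the origin
(circular molecules); control fragments never span an amplicon end
(linear molecules). Each fragment's origin, strand class and duplicate
flag go to a sidecar TSV — not the FASTQ headers — so the aligner cannot
cheat, and the same seed yields byte-identical FASTQ output.

The truth table records drawn methylation states per unique molecule at
*read-observed* positions only: cytosines in the middle of an insert
longer than two read lengths are invisible to sequencing, and counting
them would make exact truth/extraction equivalence unattainable by
construction.

Because real reference sequences are not bundled, the reference genome is
a **synthetic stand-in**: a random circular 16,569 bp sequence with
human-mtDNA-like base composition carrying exactly 435 CG dinucleotides
(870 CpG sites over both strands), i.e. calibrated to the published census
of the human mitochondrial reference; tumor-genotype stand-ins add
CpG-creating substitutions at nt 9054 and 11912 so the profile diff
reproduces the published genotype difference at nt 9053–9054 and
11911–11912. What passing tests on these data do show: the census,
alignment, calling, normalization and statistical machinery are correct
under the stated noise model. What they do not show: anything about real
tumor methylomes — the generator has uniform coverage, no adapter
contamination or quality decay, no indels, no nuclear-pseudogene (NUMT)
contamination, and site-independent methylation (no co-methylation
structure along molecules).

## Validation experiment sizes

The experiments behind `scripts/acceptance.py` and the end-to-end tests
use these problem sizes, chosen as a balance between statistical
resolution and desk-scale runtimes: methylation recovery runs the full
16,569 bp genome at 500× (one sample plus both controls, ~28k fragments
each); aligner origin recovery uses 8,000 error-free fragments;
ANOVA calibration uses 2,000 null simulations of 3 groups × 3 replicates;
differential recovery injects +15-point effects at 10 CpG sites of a
4,000 bp genome at 500× with 3 groups × 3 replicates. With the per-site
call coverage of ~235× at that depth, a 15-point shift is a ≈ 6.5σ effect
for the Welch test at n = 3, while the joint rule holds null-site false
positives well under 5% (a null site must exceed both p < 0.05 and a
5-point difference, about 2.2σ of its sampling noise).

## Numerical conventions

Coordinates are 1-based, inclusive, on the plus strand throughout; a
minus-strand cytosine is reported at the position of its plus-strand
guanine. Degenerate Beta requests (mean 0 or 1, or concentration 0) are
treated as point masses. Percentages are clamped to [0, 100] after
normalization. Star annotation uses strict inequalities. ANOVA/t-test
p values at zero-variance sites take the p = 1 convention rather than
propagating NaN. Annotation intervals may wrap the origin; the first
matching feature wins and overlaps are warned about once.
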