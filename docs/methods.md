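# Methods

## Locus geometry

An amplicon locus is defined by its reference sequence and the unique
occurrence (either strand) of a 20-nt protospacer immediately followed by an
NGG PAM. Only NGG is accepted: the pipeline targets SpCas9-family enzymes.
The expected cleavage position is the canonical SpCas9 blunt cut 3 bp 5′ of
the PAM, i.e. the inter-base coordinate between protospacer positions 17 and
18. Nickases (D10A cutting the guide RNA-paired strand, H840A the displaced
strand) and nickase fusions are windowed at the same reference coordinate:
the strand nicked does not change where editing outcomes appear in reads, and
the exact H840A nick offset (3 vs 4 nt from the PAM) is irrelevant at the
10-bp window scale.

The indel quantification window is the half-open interval
`[cut − w, cut + w)` with `w = 5` by default (10 bp total). Protospacer
coordinates in user-facing APIs run 1–25 with the PAM occupying 21–23;
internally everything is 0-based, half-open on the reference top strand.

## Donor design

Donors are single-stranded 100-mers centred on the protospacer midpoint
(truncated only by amplicon ends), carrying one target SNP given in
protospacer coordinates, and optionally a PAM-blocking replacement (e.g.
TGG→TTT) of which only the positions that actually differ from the native
PAM are recorded. "Forward" orientation means the same sense as the sgRNA;
"reverse" is its reverse complement. A PAM replacement identical to the
native PAM warns and is dropped rather than failing, since it is a no-op,
not a design error. If a requested target edit falls inside the PAM-block
triplet, the edit allele wins at that position. Positional series (one donor
per protospacer position, doubled into non-blocking/blocking sets when a
block is requested) default to a fixed transversion rule for the donor
allele — A→C, C→A, G→T, T→G — chosen so the donor base always differs from
the reference; any other rule can be supplied.

## Read simulation

The simulator emits single-end reads as full effective amplicons: amplicons
longer than 270 nt are trimmed to the 250-nt subsequence centred on the
quantification window, mirroring 230–270-nt single-end sequencing; shorter
amplicons are used as-is. Read classes are drawn in one multinomial per
sample from the mixture (unmodified / HDR / indel / HDR+indel), with an
optional contamination fraction of bare donor oligos layered on top —
the in-silico stand-in for donor ssODN molecules priming the PCR, which
real protocols remove by size-selective purification. HDR reads carry all
donor substitutions; indel reads carry exactly one insertion or deletion
whose anchor is uniform over the window, with type equiprobable and size
geometric (mean 3, capped at 20) by default — the nick-repair indel
spectrum is not characterised, so this law is an explicit stand-in and is
configurable. HDR+indel reads apply the donor substitutions first, then one
windowed indel (the order is observationally irrelevant; fixed for
determinism). Sequencing noise is independent per-base substitution (uniform
over the three alternatives); no quality model, paired ends, PCR duplicates
or chimeras are simulated, because the analysis uses none of those signals
(qualities are written as constant 'I'). One seeded RNG stream drives the
whole sample, so identical parameters give byte-identical FASTQ.

What passing tests on these simulations do **not** show: performance on real
nick-repair indel spectra (sizes/positions may differ from the geometric
stand-in), on quality-correlated error patterns, or on loci whose true
amplicon differs from the configured reference.

## Alignment

Reads are aligned globally (Needleman–Wunsch/Gotoh, numba-accelerated) with
affine gap costs; a gap of length L costs `gap_open + L·gap_extend`.
Defaults are match +2, mismatch −3, gap open −5, gap extend −2, chosen so a
single-SNP HDR read at amplicon read lengths always scores better as a
mismatch than as gaps; all four values are configurable. Ties are broken
deterministically, preferring match/mismatch over deletion over insertion,
both at the final cell and at every traceback step. `N` mismatches
everything, including `N`.

A read carrying both donor SNPs and a nearby indel can misalign against the
unedited reference: the optimal alignment may absorb the SNPs into the indel
and shift its anchor. The classifier therefore also aligns such reads to the
expected HDR allele (reference with donor substitutions applied; identical
length, so all coordinates agree) and classifies on the better-scoring
alignment, ties favouring the reference. The second alignment is skipped
when the reference alignment is gapless and matches the reference at every
donor position, where it provably cannot be beaten.

## Window-indel semantics

Indel placement inside repeats is ambiguous: score-equivalent alignments
anchor the same event at different positions, and which one the traceback
returns is an artefact of tie-breaking. An indel is therefore counted as
"in the window" if **any** score-equivalent placement intersects it: for a
deletion, its deleted reference interval shifted left/right through equal
flanking bases; for an insertion, its inter-base anchor rotated through
matching flanks. Insertions count when an equivalent anchor lies in
`[start, end)` — an anchor exactly at the window start is inside, one at the
(exclusive) end is not. Deletions count when any equivalent placement
overlaps the window by at least one base.

## Classification and filtering

Decision order per read: DISCARDED if the aligned span (first to last
reference position covered by read bases) is under 90% of the amplicon —
the read-coverage analogue of physical size selection, rejecting 100-nt
donor oligos against ≥230-nt amplicons with ample margin; then INDEL if any
window indel (HDR + indel ⇒ INDEL, always); then HDR if every *target* SNP
matches the donor allele — PAM-block incorporation is reported per read but
not required for the HDR call, and partial incorporation of only the PAM
block is UNMODIFIED; else UNMODIFIED. Substitutions outside donor positions
never affect the class, so sequencing errors are tolerated; indels outside
the window leave a read eligible for HDR/UNMODIFIED. A position deleted in
the read gives an undetermined SNP call that never matches the donor.
Unalignable (e.g. empty) reads are DISCARDED with a logged reason.

## Quantification

Percentages are fractions of the non-discarded read population (read % is
equated with cell %; allele copy number and transfection efficiency are out
of scope). The corrected HDR percentage multiplies the indel-free HDR rate
by the indel-free fraction of the population, undoing the enrichment caused
by removing indel reads before scoring HDR. With counts this reduces to
`100·n_hdr/n_kept`, but the correction is exposed as its own operation on
percentages so it can be applied to externally tabulated data. The HDR:indel
ratio divides corrected HDR % by indel %; it is NOT_REPORTED — a first-class
sentinel, never a silent zero — when HDR is below the mode threshold (1% or
0.1%), and also when indel % is exactly 0 with HDR above threshold (division
undefined; logged). Replicate aggregation reports mean and n−1 sample sd;
for ratios, NOT_REPORTED replicates are zero-filled into the mean so site
averages are not inflated. If every non-discarded read carries an indel, the
indel-free HDR percentage is defined as 0. All arithmetic is carried at full
float precision; rounding (1 decimal for percentages, 2 significant figures
for fold changes) happens only at report time.

## Comparison statistics

Student's pooled-variance two-tailed t-test (not Welch's) with
df = n_a + n_b − 2, suiting small equal-size replicate groups; zero pooled
variance degenerates to p = 1 (equal means) or p = 0 (unequal, logged).
Significance bands follow the figure convention: `*` 0.01 < p < 0.05,
`**` 0.001 < p < 0.01, plus `***` for p ≤ 0.001 to cover the range the
two-band convention leaves undefined; `ns` at p ≥ 0.05. No multiple-testing
correction is applied — comparisons are reported per pair, which is a known
caveat. Regression is ordinary least squares with r² the squared Pearson
correlation and the two-tailed slope p-value.

## Validation problem sizes

The test suite validates exact truth recovery on noise-free simulations of
10,000 reads per mixture across 18 mixtures spanning HDR 0–15%, indel 0–25%
and HDR+indel 0–5%; parameter recovery within 3 binomial standard errors at
n = 10,000 under 0.1% per-base error over 3 seeds; alignment optimality
against an independently coded recursive oracle (itself checked against full
path enumeration at tiny lengths) on 500+ random pairs of length ≤ 8; and a
donor-contamination background below 0.2% apparent HDR at 30% contamination.

## Known limitations

- The geometric indel size law is a stand-in, not an empirical nick-repair
  spectrum.
- The coverage filter models size selection as a hard span threshold; real
  gel/bead selection is a smooth size distribution.
- Read % = cell % ignores ploidy and mosaicism.
- Global alignment assumes reads span (nearly) the whole amplicon; partial
  reads other than donor contamination are simply discarded.
- Off-target sites are handled only as additional configured amplicons;
  there is no site discovery.
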