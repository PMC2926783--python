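# Methods

This note documents the models, conventions and design choices behind each
stage of `lincons`, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open; 1-based positions appear
only in human-readable text. BED is the single annotation dialect: the
pipeline's annotation inputs (transcript models, conserved elements) are
natively BED-shaped, so one well-tested BED12/BED6 reader is preferred over
additional GTF/GFF parsers. FixedStep wiggle tracks are accepted through a
pre-conversion utility (`wiggle_to_bedgraph`), keeping one internal track
representation. FASTA and MAF go through Biopython. Parsers reject rather
than repair: every error names the offending line or record. One deliberate
leniency: a BED12 line whose last block ends short of chromEnd is accepted,
with the locus interval taken from the block span (blocks extending *past*
chromEnd remain an error) — some exporters emit such lines, and the block
span is the only coherent locus extent for them.

The score track is held as one dense float array per chromosome with NaN
for positions absent from the track. phastCons-style tracks legitimately
omit unalignable bases, so missing positions are excluded from averages by
default; `impute_zero=True` switches to the treat-absent-as-zero convention
appropriate for element-derived tracks, where absence means "not conserved".

## Locus selection

A candidate lncRNA is removed when (a) any of its exons overlaps any
protein-coding exon, or (b) its distance to the nearest coding locus is
strictly below `min_distance` (default 5000 bp; a gap of exactly 5 kb
keeps the transcript). Overlap is tested at exon level (the stricter
reading); proximity at locus level, strand-ignored, because the hazard the
rule guards against — mistaking UTRs or alternative transcripts of coding
genes for independent noncoding loci — applies on both strands. The default
distance is the gap between locus intervals; `distance_mode="tss"` measures
TSS-to-TSS instead for sensitivity analyses.

Element overlap statistics union all elements before counting, so no base
is double-counted and duplicating the element input changes nothing.
`exonic_fraction` divides covered exonic bases by total exonic bases;
`genic_fraction` divides covered locus bases by locus length. A transcript
"harbors constrained sequence" when its genic overlap is positive — any
positive overlap counts, with no minimum. The cohort summary reports the
constrained count and percentage, both mean fractions, and a histogram of
genic fraction in 2 %-wide bins.

## Metagene conservation profile

Every multi-exon locus (single-exon transcripts are excluded) is split into
six strand-aware regions: upstream flank (default 200 bp, matching the core
promoter definition; configurable for exploratory use), first exon, introns,
middle exons, last exon, downstream flank. Regions are rescaled to
`samples_per_region` slots (default 200):

- length L ≥ k: slot i holds the score at base round(i·(L−1)/(k−1));
- L < k: each base lands in slot round(pos·(k−1)/(L−1)); slots holding
  several bases average them, empty slots are missing.

Scores are *sampled*, never interpolated — a slot holds a real track value
or is missing. Averaging across loci is locus-weighted: each locus
contributes at most once per slot regardless of length, and for the pooled
regions (introns, middle exons) each feature is first rescaled individually
and the features of one locus averaged, so a locus with ten introns still
counts once. The promoter peak is the argmax of the upstream segment,
converted to bp with the region's base-per-slot scale; the upstream flank
is anchored at the TSS (offsets negative = upstream) and ties resolve to
the anchor-proximal slot.

## ECR detection

An evolutionarily conserved region is a reference-genome segment of at
least `min_length` bases (default 100) with identity at least
`min_identity` (default 0.70) against the aligned second species. Windows
are measured in reference (ungapped) bases, not alignment columns, and
every offset is tested (step 1) — the definition quantifies over segments,
not a grid. A reference base aligned to a gap or to N counts as a mismatch
(conservative for assembly gaps); soft-masked lower-case bases compare
case-insensitively, since masking is not identity-relevant.

Qualifying windows that overlap or abut are merged, and each merged cluster
is then trimmed to its best-scoring subsegment of length ≥ `min_length`
under the per-base score (match − min_identity). Trimming is needed because
the raw union systematically overshoots: on a 50 %-identity background a
window can start up to half a window-length before a conserved segment and
still clear 70 %, so pure union-of-windows boundaries extend ~w/2 into
background on each side and a 150 bp segment would be reported as ~250 bp.
The trimmed segment provably has identity ≥ the threshold over its whole
extent, so every reported ECR itself satisfies the ≥ 100 bp / ≥ 70 %
definition; `n_windows` (qualifying windows in the cluster) is reported for
transparency. All threshold comparisons and trim tie-breaks use exact
integer arithmetic (the threshold as a rational), making results bit-stable
and identical to the brute-force reference scanner. Ties prefer the longer,
then leftmost segment.

## Ortholog identity

Overall identity of a cDNA pair is computed the way summed BLASTn local
alignments are usually read, without re-implementing seeded heuristics:
exact affine-gap local alignment (Biopython `PairwiseAligner`) under the
BLASTn nucleotide defaults — match +2, mismatch −3, and a gap of length k
costing 5 + 2k — finds the best hit; its query span is masked; the search
repeats until the best score falls below `min_score` (default 30,
≈ 15 exact matches, comfortably above the expected maximum chance score at
cDNA scale). Equal-scoring optima tie-break by smallest query start, then
smallest subject start. The summary percent is
100 × (summed identities over the accepted, query-disjoint hits) / query
length. The measure is deliberately asymmetric — the denominator is always
the reference-species transcript — and query masking guarantees the
numerator can never exceed it. Exact dynamic programming is acceptable at
cDNA scale (≤ ~10 kb × 10 kb); N matches nothing.

Windowed identity profiles slide a fixed window (default 100 columns, step
10) along alignment blocks and report, per non-reference row, matches /
window columns, mapped to the reference coordinates of the window's first
and last reference bases; windows containing no reference base are skipped.

## Coding assessment

ORFs are scanned on the forward strand only (inputs are oriented cDNAs),
all three frames, ATG to the first in-frame stop. An ATG with no downstream
stop yields an incomplete ORF counted at its current codon length, since
cDNA truncation is common. ORFs containing N are skipped; ties go to the
5′-most start. The coding-capacity flag `long_orf` is strict: aa_length
> 100.

dN/dS uses Nei–Gojobori (1986) counting with Jukes–Cantor correction — a
fully specified, desk-verifiable method adequate for testing departure from
neutrality, which is the only use this pipeline puts it to; reports label
the method explicitly. Sites: each codon's nine single-nucleotide mutants
are enumerated, mutants that are stops are excluded, and counts rescale so
n + s = 3 exactly. Differences: per differing codon pair, substitutions are
classified by averaging over all orderings that avoid stop intermediates;
pairs whose every pathway crosses a stop are dropped entirely (sites and
differences) and counted in a QC field, as are gapped codon pairs. A
trailing stop codon pair is tolerated and excluded. pX = Xd/X;
dX = −(3/4)·ln(1 − 4pX/3), undefined for pX ≥ 3/4; the ratio is undefined
when dS is 0 or undefined — undefined values are reported as such, never
imputed. The estimate is symmetric in its two sequences.

## Motif annotation

IUPAC patterns are matched case-insensitively on the forward strand with
overlaps allowed; '|' in a pattern (as in MAG|GTRAG) is annotation only.
The poly(A) report scans AATAAA then the ATAAA variant (priority
configurable); a lower-priority hit lying entirely inside a higher-priority
hit is suppressed, so the ATAAA contained in every AATAAA never outranks
it. `offset_3p` counts from the motif's first base to the 3′ terminus — a
signal starting 30 nt from the end has offset 30 — with
`measure_from="end"` available for the to-the-last-base convention. The
splice table reports, per intron in transcript orientation, the terminal
dinucleotides (GT..AG flag, strand-aware via reverse complement) and
whether the last 3 exonic + first 5 intronic bases match the U2 donor
consensus MAG|GTRAG; introns under 4 nt are flagged, not scored.

## Synthetic data

The generator produces, deterministically under (seed, config):

- **Annotation**: coding genes and lncRNAs alternating along chromosomes,
  exon counts 2–5, exon lengths 80–300 bp, introns 200–1500 bp. Configured
  fractions of lncRNAs are planted in violation of the filters (default
  20 % within 5 kb of the preceding coding gene, 10 % overlapping a coding
  exon); `forced_gaps` pins exact distances for boundary tests. Ground-truth
  filter labels are emitted, computed by an internal brute-force scan
  independent of the production filter.
- **Conservation track**: independent uniform jitter (±0.03) around a
  background mean of 0.05 — the simplest noise model with controllable
  signal-to-noise; the analysis nowhere assumes autocorrelation. On top:
  a Gaussian bump (σ = 10 bp, giving an unambiguous argmax) of height 0.19
  centered 43 bp upstream of each lncRNA TSS, strand-aware; bumps of 0.12
  spanning ±20 bp of each internal splice site; and plateau segments
  (+0.25) inside a random subset of exons (probability 0.6, 20–80 % of the
  exon), which give the score distribution the bimodality that discrete
  conserved elements require. Elements are the maximal runs above the score
  threshold that puts the covered fraction of lncRNA exonic bases at the
  configured target (default 0.30, enforced within ±0.05 — a flat track
  that cannot reach the target is an error, not a silent repair).
- **Alignments**: one two-species block; per-column match probability
  equals the background identity (default 0.5) outside planted segments and
  the segment identity (default one 150 bp segment at 0.9) inside; gap
  columns at rate 0.02 outside planted segments only, so planted identities
  are exact by construction. Ground-truth segment coordinates are emitted.
- **Ortholog pairs**: homology is block-structured, as in real ortholog
  pairs. Conserved blocks (within-block identity 0.95) cover just enough of
  the 2 kb query that the expected identical-aligned fraction equals the
  configured value; the subject is the ordered concatenation of mutated
  block copies joined by short (8–19 bp) unrelated spacers, so sequence
  outside the blocks is simply absent from the ortholog and cannot sit on
  the query diagonal — positionally parallel "noise" would let local
  alignment harvest ~25 % chance matches and bias recovered identity
  upward. When the requested identity meets or exceeds the block identity,
  the whole sequence becomes one block at the requested per-base identity.
  Short indels (1–10 bp) fall only inside non-3′ blocks. The conserved 3′
  block is copied exactly and carries an ATAAA signal placed exactly 30 bp
  from both 3′ ends (flanking bases are guarded so no accidental AATAAA or
  downstream ATAAA displaces it).
- **Neutral codon pairs**: each site of the derived copy mutates with
  probability μ (default 0.1) uniformly to another base, no selection;
  codons that would become stops are redrawn. The dN/dS of such pairs is
  ≈ 1.

What the generator does *not* emulate: realistic base composition or repeat
families, autocorrelated conservation noise, phylogenetically simulated
multi-species evolution, transition/transversion bias. Passing tests
therefore demonstrate that the pipeline recovers planted structure of the
kind and scale it targets, not that it is robust to every artefact of real
genomes.

## Verification and problem sizes

Six core operations (selection filter, overlap fractions, ECR scan,
windowed identity, IUPAC scan, NG86 counting) are checked for exact
agreement with independent brute-force implementations (per-base counting,
exhaustive enumeration, O(n·m) Gotoh dynamic programming, Biopython-based
codon translation) on hundreds of randomized small instances. Stochastic
recovery checks run at desk scale, chosen to keep the full suite in the
low minutes on one CPU while leaving comfortable statistical margins:
promoter-peak recovery on 20 seeded cohorts of 200 multi-exon loci
(median |offset error| ≤ 5 bp, median height error ≤ 0.03); planted-ECR
recovery with ≥ 80 % reciprocal overlap in ≥ 95 % of 100 seeded trials;
neutral median dN/dS within [0.8, 1.25] over 50 replicates of 300 codons;
and ortholog identity within ±5 percentage points of the planted 30/50/90 %
at 2 kb. `scripts/acceptance.py` recomputes all of these from scratch under
a caller-supplied seed.

## Known limitations

- Genome-scale cohort statistics depend on the input catalog; the shipped
  defaults characterize the synthetic study conditions, not any particular
  genome release.
- The overall-identity percent depends on the masking/denominator policy;
  both are fixed and documented above precisely because BLAST-style
  summaries are otherwise ambiguous.
- NG86 with Jukes–Cantor ignores transition/transversion bias and codon
  frequencies; for hypothesis tests beyond "≈ neutral", a likelihood
  codon model is the right tool.
- The dense per-chromosome track representation favours simplicity; for
  chromosome-scale real tracks a compressed or windowed store would be the
  natural extension.
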