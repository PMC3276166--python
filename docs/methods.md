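# Methods

This note records the models, parameter choices, and numerical conventions
behind `iesmap`, and what the simulation-based tests do and do not
demonstrate about real data.

## Reference model: the conMAC

The alignment reference is a single pseudo-chromosome: somatic (MAC)
assembly contigs ordered by decreasing length — ties broken
lexicographically by name for determinism — and joined with 10 kbp blocks
of N. N never scores as a match, so no alignment, and therefore no
breakpoint, can cross a contig boundary; positions inside spacers are
treated as edges. Spacers are placed only *between* contigs. Assembly
components that carry no elimination signal of interest (the rDNA
minichromosome, the mitochondrial genome) are excluded by name before
size-ordering. All internal coordinates are 0-based half-open; 1-based
conventions are applied only at SAM and GFF3 boundaries. A one-end read
whose breakpoint falls within `edge_margin` (default 100 bp) of a contig
end is excluded from evidence: at that distance a clip is more plausibly an
assembly-edge artifact than an excision junction, and 100 bp comfortably
exceeds breakpoint placement jitter.

## Read trimming

Sanger reads are vector-trimmed (exact terminal matches of ≥ 10 bp;
internal hits flag the read without altering it) and then quality-trimmed.
"Average quality ≥ Q20" is interpreted as the **longest contiguous window**
whose mean phred score (phred-scale averaging) reaches the threshold,
tie-broken leftmost; this is deterministic and reduces to whole-read
behaviour whenever the whole read qualifies. Reads whose best window is
shorter than 50 bp are discarded: shorter fragments cannot support the
combination of a >10 bp clip and a uniquely mapping anchor. The window
search is verified against an exhaustive all-substrings oracle in the test
suite.

## Built-in aligner

The built-in aligner serves desk-scale and synthetic data; production-scale
data can be aligned externally and ingested as SAM. It indexes exact
20-mers of the conMAC, groups seed hits by diagonal, and extends each
diagonal gaplessly in both directions under an X-drop criterion
(match +1, mismatch −3, X = 20, minimum alignment score 40). The aligner is
deliberately **gapless**: the read simulator injects substitution errors
only, and the quantity that matters downstream is where an alignment
*ends*, which a maximal-scoring gapless extension pins down exactly. Gap
penalties, and indel-containing alignments generally, are the province of
the external-aligner route (`ingest_sam` parses clips from any CIGAR and
flags internal indels ≥ 10 bp as discontinuities); an agreement test runs
`bwa mem` on simulated reads and requires ≥ 90% per-read category agreement
with the built-in route.

Read coordinates are strand-normalised (expressed on the reverse complement
for minus-strand hits), so `left_clip` always means unaligned sequence on
the reference-left; the L/R logic downstream is thereby strand-agnostic.
Overlapping alignments of the same read region are kept as secondary
records; a read is a **multi-mapper** when a secondary hit at a different
locus scores ≥ 0.95× its primary hit. The original study segregated
multi-mappers without stating its criterion; the score-margin rule is this
package's documented stand-in, and multi-mapper evidence is never used for
site calling.

## Site calling

One-end breakpoints are clustered per side by single linkage with a 9 bp
gap, summarised by the lower-median coordinate (the published procedure
does not state how multiple same-side endpoints were reduced; the median is
robust and deterministic). An L cluster ending at `l` and an R cluster
starting at `r` converge when their MAC-matching overlap `l − r + 1` is at
most 9 bp (retained microhomology) **and** their gap `r − l − 1` is at most
9 bp (alignment-end erosion); the overlap bound is the published criterion,
the symmetric gap bound is this package's completion of it. Any site
spanned by a unique fully mapped read with ≥ 10 aligned bp on each side is
vetoed. The genome-wide estimate is `round(n_win1 / f²)`.

## Junction analysis

Microhomology search is exact-match only — at 3–4 bp, mismatch tolerance is
meaningless — and reports the leftmost of equally long placements. For
called win1 sites the retained microhomology is read directly off the
reference as the overlap of the L- and R-aligned intervals; the
string-level decomposition (`compute_microhomology`) additionally verifies
against germline boundary sequence and is checked against a brute-force
maximality oracle. IES assembly joins the longest L and R clip by exact (or
≥ 95% identity) suffix–prefix overlap of ≥ 20 bp; clips that ran past the
IES into MAC-destined sequence are first trimmed where their termini match
the reference beyond the opposite breakpoint (minimum 5 bp of match, so
that chance 1–4 bp agreements do not erode genuine IES sequence). Without
an overlap the longest clip length is reported as a lower bound.

## Context annotation

Gene models come from GFF3. Two filters approximate the original study's
manual curation of improbable models: any exon < 30 bp or any intron
> 1 kbp marks a model implausible, and implausible models are ignored
during annotation. A site window overlapping an exon is labelled by that
exon's strand-aware ordinal (5′ / 3′ / Mid / Single), with a `Jxn` prefix
when the window straddles the exon/intron boundary; inside a gene but
outside exons is intron; otherwise intergenic. Overlapping genes each
contribute a label.

## Simulator: what it emulates

Genomes are i.i.d. base draws at 75% AT (A/T and G/C split evenly),
matching the strong AT bias of ciliate genomes. IES junction positions are
stratified-uniform: contigs receive counts proportional to usable length,
and one position is jittered uniformly inside each equal-width slot, which
guarantees the 2 kbp minimum spacing by construction. Short-class IES
(100–500 bp total) carry a 3–4 bp microhomology containing TA (the full
TTAA with probability 0.75, echoing its observed preponderance) duplicated
at both germline boundaries and retained once in the somatic junction;
long-class IES (1–3 kbp) have blunt boundaries plus a small set of
alternative cut points (default 3, offsets ≤ 15 bp) modelling junction
heterogeneity. Reads are paired off ~N(8000, 800) bp fragments with
~N(750, 50) bp read lengths, a plateau-then-decay quality profile, and
substitution errors drawn per base from the quality values scaled to the
configured mean rate (default 10⁻³, a post-trim Q20+ regime).

**Junction non-extendability.** The IES core is rejection-sampled until no
gapless local extension (+1/−3) can carry an alignment across either
junction in either genome. Without this constraint the *actual* maximal
microhomology at a junction would occasionally exceed the planted one
through chance base agreement, making truth labels wrong and breakpoints
ambiguous by a few bp. This is a property of the ground truth, not a
relaxation of the caller.

**Coverage calibration.** A read yields one-end evidence for a junction
side when it anchors ≥ 40 bp (the aligner's score floor) on the somatic
side, clips > 10 bp into the IES, and does not reach ≥ 40 bp across it.
For IES longer than a read this start-position window is exactly
`read_len − 50` bp, so the fragment count is set per contig by inverting
`f = 1 − exp(−λ)` with `λ = 2·n_frag·w/(L − F)`. Each junction side is then
covered with probability *f* and the win1 recall converges to *f*²; the
coverage-law experiment uses long-class IES and fixed read length, where
the calibration is exact. `f = 1` switches to a guarantee mode (two planted
qualifying reads per junction side plus ~1× uniform background), the
full-coverage limit in which recall must be exactly 1. Short IES present a
narrower qualifying window and are detected less often at equal *f*; the
law is a property of read-spanning IES.

**What passing tests do not show.** The simulator draws i.i.d. bases: it
has no repeats beyond the optional planted element, no cloning bias or
insert-size instability, no chimeric clones, and no indel sequencing
errors. Real data adds multi-mapping ambiguity, library artifacts inflating
the discontinuous class, and alignment-end noise beyond the ±9 bp window;
the published read partitions can therefore not be reproduced from
synthetic data, and the acceptance checks instead verify the in-table
worked examples and the statistical structure of the method.

## Problem sizes

The test suite runs an error-free end-to-end experiment on a 500 kbp
somatic assembly with 60 mixed-class IES at *f* = 0.5, and the coverage-law
experiment on a 500 kbp single-contig assembly with 200 long-class IES at
*f* ∈ {0.25, 0.5, 1.0} × 10 seeds (2,000 junction trials per fraction,
compared with *f*² at 3 binomial standard deviations). These sizes give
stable statistics at interactive runtimes; all simulations are seeded and
byte-reproducible.

## Known limitations

* The built-in aligner does not model indels; indel-containing reads must
  come through the SAM ingest route.
* Mate-pair information is not used jointly: each read is classified
  independently, as in the original procedure.
* Single-linkage breakpoint chains can in principle exceed the 9 bp window
  over many reads; with clean data the chains are tight, but dense noisy
  data could merge neighbouring sites.
* Heterogeneous-boundary junction variants are generated and compared at
  the string level; the pipeline itself calls one canonical junction per
  site, as a single somatic assembly realises only one excision outcome.
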