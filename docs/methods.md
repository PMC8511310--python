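# Methods

This note documents the models, conventions and numerical choices behind
splicelight, and what its synthetic-data validation does and does not
establish about real data.

## Coordinate model and the reference-isoform rule

All intervals are 0-based half-open on a chromosome strand; GFF3's
1-based closed convention is converted only at the file boundary. A
transcript is an ordered list of non-overlapping exons with introns of
length ≥ 1 between them; monoexonic transcripts are retained (they can be
the retaining side of an intron-retention pair).

The reference isoform of a gene is the one maximizing **spliced** (exonic)
length, not genomic span — "longest" in the sense in which transcript
lengths are usually quoted. Ties break to the lexicographically smallest
transcript id so the choice is deterministic and independent of input
order. No CDS annotation is consumed anywhere; reading frames are derived
from sequence (below).

## The event calculus

Classification of an (reference, alternative) pair is a function of the
two intron chains plus exon containment:

1. **IR** — an intron of one isoform strictly inside a single exon of the
   other (strict containment means both flanking splice sites are unused
   there). When the *reference* is the retaining member — possible under
   the longest-isoform rule — the event is still IR with
   `retained_in=ref`, and the non-reference isoform counts as the gene's
   IR isoform.
2. **ES** — an internal reference exon spanned by exactly one alternative
   intron whose two boundaries coincide with the outer splice sites of
   the exon's flanking reference introns. Multi-exon skips do not satisfy
   the outer-site condition and fall through to OTHER.
3. **AA/AD** — a reference intron and an alternative intron sharing
   exactly one boundary. The pairing must be mutually unique among the
   not-yet-explained introns and the differing interval must contain no
   complete exon of either isoform; without that guard, mutually
   exclusive exon loci would be mistyped as two splice-site shifts.
   Orientation is transcript-polarity-based: the moving boundary nearer
   the transcript 3′ end gives AA (alternative 3′ splice site), nearer
   the 5′ end gives AD — i.e. the genomic-right intron boundary on the
   plus strand is the 3′ splice site, and the mapping flips on the minus
   strand.
4. **OTHER** — all remaining unexplained introns of both isoforms are
   clustered by genomic overlap; each cluster yields one event whose
   region spans the cluster. This makes every differing isoform
   classifiable.

Rules apply in the order listed, each consuming the introns it explains.
Differences confined to the genomic endpoints of the first/last exon with
identical intron chains yield no event: alternative transcription start
and termination sites are positional, not splicing, variation.

Two symmetry properties pin the calculus down: shifting all coordinates
by Δ shifts every event region by Δ, and relabelling the strand (fixed
coordinates) swaps AA↔AD while preserving IR/ES/OTHER. Mirroring the
coordinates *together with* the strand flip describes the same molecule
and therefore preserves every event type — the test suite asserts both.
The whole calculus is additionally checked, at 10,000 random pairs per
run, against an independent brute-force oracle that enumerates
containment and boundary-sharing relations over per-base occupancy
arrays.

**Cross-tissue identity.** An isoform's identity across tissue-level
isoform sets is the pair (gene id, intron chain); terminal ends vary with
read evidence and do not split identity. The longest representative
supplies the terminal ends and events are recomputed once against the
reference, making the merge idempotent and order-invariant.

## PTC detection and NMD candidacy

The reference reading frame is the longest ATG-initiated ORF of the
reference isoform's spliced sequence ending in TAA/TAG/TGA, ties to the
5′-most start. The ORF start is projected to the alternative isoform
through its genomic position; if that base is not exonic in the
alternative isoform (or is no longer ATG), the case is reported "not
assessable" rather than guessed. Translation then proceeds codon by
codon from the projected start; `has_ptc` is true iff an in-frame stop
appears strictly before the position corresponding to the reference stop
codon. A frame-preserving retained intron without stops yields
`has_ptc=false` with the note "in-frame insertion".

NMD candidacy uses the canonical 50-nt rule: the stop must lie more than
50 nt upstream of the alternative isoform's last exon–exon junction
(measured from the end of the stop codon). Monoexonic alternatives have
no junction and are never candidates. PTC assessment is only performed
for intron-retention isoforms; frameshifts arising from other event types
are out of scope and reported as not assessed.

## Differential expression

The NB Wald test is deliberately simple and fully documented rather than
a re-implementation of any specific tool:

- **Size factors**: median-of-ratios over features with all-positive
  counts; upper-quartile fallback (scaled to geometric mean 1) with a
  warning when no such feature exists.
- **Dispersion**: per-feature method of moments,
  `α = (pooled within-group variance − mean)/mean²`, floored at 1e-8. The
  within-group pooling keeps a real condition effect from inflating the
  estimate. There is no dispersion trend or shrinkage, no Cook's
  filtering, no independent filtering.
- **Effect size**: `log2((m_test + 0.5)/(m_base + 0.5))` of normalized
  group means; the 0.5 pseudocount keeps zero-mean features finite.
- **Inference**: delta-method standard error
  `SE = sqrt(Var(m_t)/m̃_t² + Var(m_b)/m̃_b²)/ln 2` with
  `Var(m) = (m + αm²)/n` and `m̃ = m + 0.5`; the Wald statistic is
  referred to a Student t with the pooled within-group degrees of freedom
  (n_t + n_b − 2). At triplicate depth the variance estimate carries few
  degrees of freedom, and a normal reference is badly anticonservative
  (measured raw type-I error ≈ 12% at nominal 5%); the t reference
  restores calibration (≈ 5% raw, null BH discovery fraction
  indistinguishable from zero at 5,000 features). Features with zero
  counts everywhere get p = 1.
- **Multiplicity**: BH step-up within each contrast separately; NaN
  p-values propagate and are excluded from the test count. Significance
  is `padj < 0.05` by default.

Expression thresholding is strict: a feature is expressed iff
`TPM > 1.0` (a value of exactly 1 is not expressed), and condition-level
expression uses the mean TPM across that condition's replicates. TPM uses
the spliced length as effective length; fragment-length corrections are
out of scope. The DE-fraction comparison between feature classes is a
Pearson chi-squared on the 2×2 table, 1 df, no continuity correction.
Pathway heatmap matrices are per-condition means of log2(TPM+1), z-scored
within rows (constant rows map to zero), with reference isoforms flagged
by a `.ref` suffix.

## GO enrichment

Each term with at least `min_term_size` (default 10) background members
in the universe is tested with the hypergeometric upper tail, computed in
log space via the survival function for numerical stability at the tail;
BH is applied across the tested terms only. The mapping is used exactly
as supplied — **no GO DAG propagation is performed**, so annotations must
be pre-propagated if ancestor-term semantics are wanted. The universe is
whatever background gene set the caller supplies.

## Synthetic data: what it emulates

The generator inverts the event calculus to plant ground truth:

- **IR**: fuse two exons across an intron. Because the retaining isoform
  would then out-length the reference, the alternative's terminal exon
  ends are trimmed (a no-event difference) so the designated reference
  stays longest — the planted truth survives re-derivation of the
  reference after file round-trips.
- **ES**: delete an internal exon. **AA/AD**: move one intron boundary
  3–60 nt into the adjacent exon, respecting transcript polarity and
  strand; shifts are multiples of 3 half the time so both
  frame-preserving and frameshifting retention arithmetic is exercised
  downstream. **OTHER**: swap an internal exon for a novel exon inside
  the downstream intron (a mutually exclusive exon pair).

Event-type and tissue-overlap quotas are allocated by largest remainder,
so realized proportions equal the configured mix exactly at any size
where the mix is representable — this is what lets recovery tests assert
planted proportions exactly. Defaults emulate a light-response study
design: five conditions × 3 replicates, NB dispersion 0.1, log-normal
baseline means
(location 4.0, scale 1.0 on the log scale, median ≈ 55 counts), library
size factors uniform in [0.7, 1.3], an event mix led by IR (0.49), and a
four-tissue overlap design with a shared core. The default effect plan
up-regulates IR isoforms under blue and red light more often than it
down-regulates them, gives non-AS genes a smaller DE fraction, and plants
antagonistic reference-down/IR-up pairs (|log2FC| = 3) in a handful of
genes — the regulatory pattern of interest in light-response studies.

Coding-genome construction writes each reference isoform's spliced
sequence as ATG + non-stop codons + TAA so the longest-ORF rule recovers
a frame spanning the transcript; dedicated PTC cases carry ≥234-nt T-free
UTRs (T-free sequence can contain neither ATG nor stop codons, making the
central ORF provably unique) and, for the guaranteed-no-PTC mode, a
codon-aligned, length-divisible-by-3, T-free retained intron.

**What passing tests do not show.** The generator produces clean single
events per isoform at comfortable genomic spacing, uniform base
composition, no overlapping genes, no unannotated transcription, no
splice-site motif realism, and NB counts with a single shared dispersion.
Perfect recovery here demonstrates the correctness of the coordinate
arithmetic and the statistical calibration of the tests — not robustness
to noisy isoform discovery, mis-assigned gene ids, or dispersion
heterogeneity in real libraries.

## Numerical and design choices

- Tie-breaks are lexicographic everywhere a tie is possible (reference
  selection, ORF starts at equal length via 5′-most, output orderings),
  making every pipeline output byte-reproducible under a fixed seed; all
  randomness flows from one seed through per-stage spawned substreams.
- TPM columns sum to 1e6 exactly up to float rounding; all-zero samples
  produce all-zero TPM columns with a warning rather than NaNs.
- The event-table, summary and report writers sort rows deterministically;
  the run manifest records seed, package version and a hash of the
  scientific configuration (the output location is excluded from the
  hash).
- Problem sizes used by the validation suite: 10,000 random pairs for
  oracle equivalence, 500 genes for planted-event recovery, 1,000
  randomized IR cases for PTC equivalence, 5,000 null and 1,000 planted
  features for DE calibration, 80-gene end-to-end determinism runs —
  sizes at which every statistical check has comfortable power while the
  whole suite stays fast.

## Known limitations

- Alternative first/last exons, alternative polyadenylation, and full
  event nomenclature codes are out of scope; such structures surface as
  OTHER events or no event (terminal-end differences).
- PTC assessment requires the reference start codon to survive in the
  alternative isoform; heavily 5′-truncated isoform models are reported
  not assessable.
- The NB test's dispersion handling is intentionally minimal; at very
  small counts or strong dispersion heterogeneity a shrinkage estimator
  (e.g. DESeq2/edgeR) will be better calibrated.
- GFF3 input must carry gene/mRNA/exon hierarchy with gene-id assignment
  already resolved; GTF is not auto-detected.
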