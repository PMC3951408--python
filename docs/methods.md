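# Methods

## Model

`nmdscreen` treats a transcript purely as its spliced sequence, an
ordered exon partition, and an annotated CDS. The operative surveillance
model is EJC-dependent NMD during the pioneer round of translation: an
exon junction complex sits ~20–24 nt upstream of each exon–exon
junction, translating ribosomes strip the EJCs they traverse, and any
EJC remaining downstream of the termination event triggers decay. The
package collapses this to the standard operational criterion — the
55-nucleotide rule — and never models the deposition offset explicitly:
the 55-nt window is the predicate, the deposition geometry only its
rationale.

Three classification surfaces derive from it:

1. **Classic 3′ rule.** With `j_last` the coordinate of the last
   nucleotide of the penultimate exon and `stop` the 3′-most nucleotide
   of the annotated stop codon, the transcript is NMD-eliciting iff
   `j_last − stop > T` with `T = 55`. Single-exon transcripts and stops
   in the terminal exon are immune by construction.
2. **Junction neutralization / rescue.** An ORF `[s, e]` neutralizes a
   junction `j` iff `s ≤ j` and `e ≥ j − T`: the ribosome either reads
   across the junction or terminates inside the immunity window, having
   started at or upstream of it. A *rescue unit* is a minimal (by set
   inclusion) set of 3′-UTR ORFs that jointly neutralize every junction
   strictly downstream of the annotated stop. Units are capped at three
   ORFs — the known multi-ORF architectures need at most three — and
   ordered deterministically by size, then total ORF length, then
   5′-most start.
3. **5′-UTR extension.** Scanning by the 43S pre-initiation complex is
   assumed to strip every EJC up to the first AUG encountered, so only
   junctions between the end of the *first* upstream ORF and the
   annotated ATG need neutralization, by any upstream ORF under the same
   window. Transcripts whose annotated ATG is in exon 1, or whose 5′ UTR
   contains no ORF, cannot retain an upstream EJC and form their own
   classes.

### Modeling choices deliberately left out

* ORFs starting *downstream* of a junction never neutralize it, even
  though ribosome-footprint geometry suggests some downstream reach; the
  distance range is not experimentally established, so the conservative
  rule stands.
* Post-termination 40S scanning between sequential uORFs (reported up to
  ~600 nt) is not modeled — it cannot be parameterized from sequence.
* Internal ribosome entry sites are not searched; cellular IRES
  prediction has no usable consensus.
* Non-AUG initiation is not modeled: all ORFs are ATG-initiated, and a
  codon containing N can neither open nor close an ORF.
* ORFs lacking an in-region stop are not reported; overlap between
  rescuing ORFs and the annotated CDS is forbidden (the scan region
  starts at `cds_end + 1`).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `threshold` | 55 | nt | NMD immunity window upstream of a junction |
| `strict` | `True` | — | eliciting iff distance `> 55`; `False` gives `≥ 55` |
| `min_rescue_orf_length` | 6 | nt | minimal 3′-UTR ORF (one codon + stop); no biological minimum is imposed |
| `min_uorf_length` | 99 | nt | functional-uORF candidacy cutoff; strict `>` by default |
| `uorf_length_strict` | `True` | — | `>` vs `≥` on the 99-nt cutoff |
| `evalue_cutoff` | 1e−6 | — | self-similarity significance bound (discard at `≤`) |
| `coverage_cutoff` | 0.5 | fraction | self-similarity coverage bound (discard at `≥`) |
| `positive_ratio_cutoff` | 0.5 | fraction | protein evidence: positives / protein length, strict `>` |
| `align_ratio_cutoff` | 0.8 | fraction | protein evidence: aligned / protein length, strict `>` |
| `alpha` | 0.05 | — | GINI significance level; per-dataset overrides supported |

Two comparator ambiguities are configurable rather than resolved. The
eliciting comparator is described both as "more than 55" and "55 or
more" in the literature this rule comes from; strict `>` is the default.
Likewise the 99-nt uORF cutoff coexists with a documented 99-nt
candidate, so `uorf_length_strict` exposes both readings. Multi-ORF
rescue is implemented as per-junction neutralization (each required
junction covered by at least one ORF) rather than continuous interval
coverage; per-junction neutralization is the only reading consistent
with the minimal single-ORF rescue case for a penultimate-exon stop.
uORFs overlapping the annotated ATG are excluded from 5′ analysis, by
symmetry with the 3′ no-overlap rule.

## Expression-based validation

GINI comparisons use the two-sided unequal-variance (Welch) t-test with
Welch–Satterthwaite degrees of freedom, computed by
`scipy.stats.ttest_ind(equal_var=False)` and cross-checked in the test
suite against a hand-coded implementation of the textbook formula. A
probe is NMD-sensitive iff `p < alpha` *and* mean expression rises under
inhibition — an NMD substrate accumulates when decay is blocked; the
direction requirement is a design decision, since a significant
*decrease* contradicts the stabilization model and is flagged
inconclusive rather than sensitive. Values are tested on the scale they
arrive in; the scale is recorded in the verdict metadata, never
transformed. No multiple-testing correction is applied across probes.
Probes that hybridize to more than one gene are excluded from judgment
and listed as ambiguous.

At n = 4 per arm the Welch test is mildly conservative: its true type-I
rate is ≈ 0.042 under exact normality and slightly lower under
log-normal intensities, so simulated null-call rates a little below the
nominal 0.05 are expected behavior, not a bug.

## Synthetic fixtures

The generator emits one transcript per requested architecture class with
the label guaranteed by construction, not by filtering. Two invariants
make the guarantee airtight:

* planted ORF interiors are built from A-free codons (alphabet C/G/T),
  so they contain no internal stop and no internal ATG in any frame;
* filler never emits a G immediately after an `AT` dinucleotide, the
  single rule that prevents spurious ATG trinucleotides anywhere,
  including every filler/segment seam.

Consequently every ATG in a fixture is a planted one and pairs with its
planted in-frame stop. Exon lengths are drawn from a 100–300-nt palette
(tighter per class where the planted distances require it), wide enough
to exercise both sides of the 55-nt window; planted distances include
the 45-nt near-junction case and a 100-nt eliciting case. Each emitted
transcript is re-classified before being returned (self-check loop), and
generation fails loudly if a layout cannot host the requested distances.
The same (label, seed, GC) triple is byte-identical across runs; seeding
is CRC-based, not `hash()`-based, so it survives interpreter
re-invocation.

Expression fixtures are log-normal intensities (natural-log baselines
uniform on [5, 9], log-sd 0.25 — a mid-range microarray-like noise
level) with the inhibited-arm mean multiplied by the fold change for
planted sensitive probes.

What the fixtures do **not** emulate: real RefSeq length and GC
distributions, alternative isoforms of one gene, probe cross-talk,
array normalization artifacts, and partial NMD efficiency (real
substrates escape decay at up to ~25 %). Passing the recovery tests
therefore demonstrates the correctness of the classification logic on
its own terms, not screen performance on a real transcriptome.

## Numerical and procedural notes

* All coordinates are 1-based inclusive on the spliced mRNA; ORF
  intervals include the stop codon. BED export alone shifts to 0-based
  half-open.
* The ORF scanner pairs each ATG with the first in-frame stop via a
  single right-to-left sweep (linear time); the test oracle re-derives
  the same set by an independent forward codon walk per ATG.
* Exon ordinals are found by prefix-sum bisection; a position on an
  exon's last nucleotide belongs to that exon.
* A Kozak context whose −3 base does not exist (ATG at positions 1–3) is
  negative, not an error.
* Degenerate Welch inputs: identical zero-variance groups give p = 1,
  differing zero-variance groups give p = 0; groups smaller than 2 are
  rejected.
* The screening pipeline processes transcripts independently and is
  deterministic; the funnel report counts each stage so any census can
  be reproduced from the per-transcript table.

## Problem sizes used in the checks

The acceptance script and test suite run at desk scale: 900 planted
fixtures (100 per class) for label recovery, 200 random sequences up to
2 kb for the scanner/oracle equivalence, 2000 simulated null probes for
type-I calibration and 500 probes at four-fold change (n = 6 per arm)
for power, and 100 random group pairs for the Welch cross-check. These
sizes give binomial standard errors comfortably inside the asserted
bands while keeping the whole suite under a few minutes on one CPU.

## Known limitations

* GenBank input trusts the record's own exon features in transcript
  order; records without them are discarded, never inferred, and
  genome-space CDS annotations (`join(...)` across genomic exons) are
  counted out rather than lifted.
* The rescue-unit search enumerates ORF subsets up to size 3; an
  architecture needing four or more cooperating ORFs would be reported
  as unrescued.
* Similarity/protein/domain verdicts consume parsed hit tables; the
  package does not run aligners or domain scanners, so verdict quality
  is bounded by the supplied evidence.
* The 5′ classifier assumes scanning initiates at the cap and stops at
  the first AUG regardless of its context; leaky scanning past a weak
  Kozak start is not modeled.
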