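# nmdscreen

Screening spliced human transcripts for nonsense-mediated decay (NMD)
immunity, and using that immunity to flag candidate polycistronic mRNAs.

## The problem

During splicing, an exon junction complex (EJC) is deposited ~20–24 nt
upstream of every exon–exon junction. The pioneer round of translation
strips the EJCs the ribosome traverses; any EJC left downstream of the
termination codon marks the transcript for NMD. Operationally this is the
**55-nucleotide rule**: a stop codon whose 3′-most base lies more than
55 nt upstream of the *terminal* exon–exon junction elicits NMD, while
stops in the terminal exon or within the 55-nt window are immune.

A genuinely polycistronic mRNA — one message encoding two or more
functional proteins — must survive this surveillance, so its ORFs should
jointly cover every junction under the same rule. `nmdscreen` turns that
architectural signature into a screen:

* **classic 3′ classification** — `classify_classic` computes
  `d = j_last − stop` and calls ELICITING iff `d > 55` (comparator
  configurable);
* **rescuing-ORF search** — for an eliciting transcript,
  `find_rescue_units` enumerates ATG-initiated ORFs in the 3′ UTR (all
  three frames, overlaps allowed, no overlap with the annotated CDS) and
  returns every minimal set of ORFs such that each junction downstream of
  the stop is *neutralized*: an ORF neutralizes junction `j` iff
  `start ≤ j` and `end ≥ j − 55`;
* **5′-UTR extension** — `classify_five_prime` applies the same window
  between the end of the first upstream ORF and the annotated ATG,
  partitioning transcripts into ATG-in-first-exon / no-uORF /
  uORF-immune / uORF-eliciting classes;
* **candidate filters** — minimal Kozak context (purine at −3), a
  self-similarity gate (discard when a same-gene nucleotide hit has
  e-value ≤ 1e−6 and coverage ≥ 50 %), protein evidence
  (positives/length > 0.5 or aligned/length > 0.8) and domain evidence
  (signal peptide / transmembrane alone are insufficient);
* **validation** — GINI verdicts (Welch two-sided t-test between control
  and NMD-inhibited expression; substrates rise when decay is blocked)
  and exact/partial matching of predicted ORFs against an experimental
  translation-initiation-site table.

All coordinates are 1-based inclusive on the spliced mRNA; ORF intervals
include the stop codon (an ORF `74..184` is 111 nt).

## Worked example

```python
from nmdscreen import TranscriptModel, classify_classic, find_rescue_units

# a planted bicistronic-like architecture: exons (237, 241, 153, 219),
# annotated CDS 28..549 ending in exon 3, 3'-UTR ORF spanning the
# terminal junction
from nmdscreen.synthetic_fixtures import make_transcript, ArchitectureLabel
t = make_transcript(ArchitectureLabel.BICISTRONIC_3PRIME, seed=5).transcript

v = classify_classic(t)
print(v.status.value, v.stop_to_terminal_junction)
for unit in find_rescue_units(t):
    print([f"{o.start}..{o.end}" for o in unit.orfs], unit.neutralized_junctions)
```

prints

```
eliciting 82
['562..660'] (631,)
```

— the annotated stop sits 82 nt upstream of the terminal junction
(eliciting, > 55), and a single 99-nt ORF `562..660` reads across the
terminal junction at 631, neutralizing it:
one rescue unit, transcript predicted NMD-immune, hence a bicistronic
candidate.

The same screen runs from the shell:

```sh
nmdscreen fixtures --n-per-label 10 --seed 1 --out transcripts.tsv
nmdscreen screen --in transcripts.tsv --out candidates.tsv --funnel funnel.tsv
nmdscreen census --in transcripts.tsv --out census.tsv
```

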