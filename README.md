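# rymeralign

Damage-aware seed-and-extend read alignment for ancient DNA (aDNA) against
small haplotype panels, such as mitochondrial genomes.

## The problem

aDNA fragments are short (typically 30–80 bp) and chemically damaged:
post-mortem cytosine deamination is read as C→T near the 5′ end of each
sequenced strand and, in double-stranded library preparations, as the
complementary G→A near the 3′ end. Seed-and-extend mappers require an exact
kmer match before extension can begin, so a deamination event inside a seed
silently discards the read — and because the most damaged reads are lost
first, both sensitivity and downstream damage-rate estimates are biased
(survivor bias).

## The method

`rymeralign` indexes a haplotype panel twice:

- a standard **(w,k)-minimizer index**: within every window of *w*
  consecutive kmers, the canonical kmer (forward or reverse complement)
  with the smallest Wang hash is stored with its occurrence list;
- a **RY index**: every minimizer key re-encoded over the two-letter
  purine/pyrimidine alphabet (A,G → R; C,T → Y), one bit per base. Each RY
  key maps back to the minimizer key(s) that produced it. Deamination
  (C→T, G→A) is a transition and never changes a base's RY class, so a
  damaged seed still matches in RY space.

At query time, read kmers missing from the minimizer index are retried in
RY space. A recovered candidate pair (read kmer *r* vs indexed kmer) whose
sequences disagree at *m* positions is accepted only if the posterior that
the disagreement is deamination rather than coincidence clears a threshold
*j*:

```
P(M|r) = P(r|M) P(M) / ( P(r|M) P(M) + P(r|¬M) P(¬M) )

P(r|M)  = ∏_b P(b | b_g, M),  P(b|b_g,M) = δ        if (b=T, b_g=C) or (b=A, b_g=G)
                                           1 − δ    if b = b_g
                                           0        otherwise
P(r|¬M) = C(k,m) p^m (1−p)^(k−m) with p = a·k^b   (k < 22)
        = 0.01                                     (k ≥ 22)
```

δ is the position-dependent deamination rate taken from user-supplied
per-position damage matrices (`--deam-5p` / `--deam-3p`, bam2prof-style
TSV). The prior P(M) is the `-V` flag (default 0.5). Rescued seeds join the
ordinary seed set; clustering, gapless X-drop extension, scoring and MAPQ
are identical with and without rescue, so with `-j 1.0`, `--no-rescue`, or
a zero-damage profile the output is byte-identical to the baseline aligner.

The package also ships a synthetic aDNA benchmark generator (endogenous
damaged fragments, NuMT-like decoys, random contaminants, with ground
truth) and an evaluation harness (sensitivity/specificity/F1 under a 50-bp
correctness rule; damage-profile re-estimation and RMSE).

## Worked example

```
rymer-align simulate --seed 7 -o reads.fq --truth truth.tsv \
    --panel-out panel.fa --profile-out-prefix dmg
rymer-align index panel.fa -k 15 -w 5 --all-circular -o panel
rymer-align map -x panel.min -y panel.ry -r panel.fa -f reads.fq \
    --all-circular --deam-5p dmg.5p.tsv --deam-3p dmg.3p.tsv -j 0.5 -o out.sam
rymer-align evaluate --sam out.sam --truth truth.tsv --ref panel.fa \
    --all-circular --report metrics.tsv
```

This simulates 2,000 endogenous high-damage fragments plus 1,000 random
contaminant reads on a 10 kb circular genome, indexes the panel at
(k,w)=(15,5), maps with rescue, and scores against truth. Output printed by
the commands above:

```
simulated 3000 reads (seed 7)
indexed 1 sequences: 3335 minimizers, 3178 RY keys (k=15, w=5)
reads: 3000  mapped: 1955  with rescued seeds: 572
  TP  FP   TN  FN  sensitivity  specificity       F1
1955   0 1000  45       0.9775          1.0 0.988622
```

The same run with `--no-rescue` maps 1,943 reads (sensitivity 0.9715,
F1 0.9855): rescue recovers 12 additional correctly placed reads on this
replicate without mapping a single contaminant. `rymer-align profile`
re-estimates the per-position damage matrices from the alignments.

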