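# psitekit

Read-length-aware P-site localization for ribosome profiling (Ribo-seq)
data, with the diagnostic statistics needed to judge the result.

## The problem

A ribosome protected fragment (RPF, "read") covers roughly 26–32 nt of
mRNA, but the biology lives at one codon inside it: the ribosomal
P-site, holding the tRNA attached to the nascent peptide. Locating the
P-site requires the *P-site offset* (PO) — the distance between a read
extremity and the first nucleotide of the P-site codon — and that
offset varies with read length, because footprint length reflects
ribosome conformation and nuclease trimming. A single constant offset,
or per-length offsets estimated independently, both misplace ribosomes
and smear the trinucleotide periodicity that downstream analyses
(codon dwell times, ORF discovery, frame-aware quantification) depend
on.

## The method

psitekit anchors estimation on annotated translation initiation sites
(TIS): ribosomes caught in initiation hold the start codon in their
P-site, so for reads spanning the TIS the offset is read off directly.
Estimation is a two-step algorithm over per-length occupancy profiles
f(x) of read extremities around the start codon (x = 0 at the TIS):

1. **Temporary offsets.** For each read length L, the 5′ temporary
   offset satisfies f(−5′tPO_L) ≥ f(x) for all x ∈ [−L+FL, −FL], and
   the 3′ one f(3′tPO_L) ≥ f(x) for x ∈ [FL−1, L−FL−1], where the
   flanking length FL (default 9 nt) keeps extremities too close to
   the start codon out of the search.
2. **Correction.** The optimal offset oPO is the mode of the
   read-weighted temporary offsets, taken over whichever extremity has
   the more frequent mode (5′ wins ties). Length bins whose temporary
   offset differs from the oPO are corrected to the local maximum of
   their profile closest to it; bins without usable signal fall back
   to the oPO. The two extremities always satisfy
   cPO5 + cPO3 = L − 1.

Offsets are then applied to every read, and the package computes
region occupancy vs a length-weighted uniform expectation, frame
composition, metagene profiles and end heatmaps, codon usage indices,
and two scalar scores: the **periodicity score** (% of CDS P-sites in
frame 0) and the **TIS accuracy score**
Σ<sub>x∈[0,14], 3|x</sub> f(x) / Σ<sub>x∈[−15,14], 3|x</sub> f(x),
which equals 1 when periodic signal exists only inside the CDS.

## Worked example

```python
from psitekit import (SimulationConfig, simulate_annotation, simulate_reads,
                      compute_psite_offsets)

config = SimulationConfig(seed=1)          # known offsets {26:9, ..., 32:15}
annotation, _ = simulate_annotation(config)
reads = simulate_reads(annotation, config, n_reads=50_000)
print(compute_psite_offsets(reads, annotation).to_string(index=False))
```

prints (abridged):

```
 length  n_tis_reads  tpo5  tpo3  cpo5  cpo3  opo opo_extremity
     26          302     9    16     9    16   16   three_prime
     28         1760    11    16    11    16   16   three_prime
     30          876    12    17    12    17   16   three_prime
     31          434    13    17    13    17   16   three_prime
     32          153    15    16    15    16   16   three_prime
```

Every corrected 5′ offset (`cpo5`) equals the offset the simulator
generated the reads with, and each row satisfies
`cpo5 + cpo3 = length − 1`. The global optimal offset is 16 nt from
the 3′ end — the value the dominant 27–29 nt bins agree on. See
`examples/` for diagnostics and the published worked offset table.

A thin CLI wraps the same pipeline:

```bash
psitekit simulate --out-dir sim --seed 1
psitekit offsets --bam sim/sim.bam --annotation sim/annotation.tsv --out offsets.tsv
psitekit report  --bam sim/sim.bam --annotation sim/annotation.tsv \
                 --fasta sim/transcripts.fa --out-dir report
```

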