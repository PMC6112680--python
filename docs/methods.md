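# Methods

## Model and assumptions

The estimator rests on one biological fact: a ribosome engaged in
initiation holds the start codon in its P-site. Reads spanning an
annotated translation initiation site (TIS) therefore carry the
offset between their extremities and the P-site in plain sight, and
the per-length occupancy profiles of read ends around the TIS peak at
those offsets. Everything is computed in transcript (spliced)
coordinates, 1-based and inclusive; the CDS starts at
`s = l_utr5 + 1` and ends at `e = l_utr5 + l_cds`, with the stop
codon counted as part of the CDS (GTF `stop_codon` features are
merged into the CDS span on load; users working with annotations that
exclude the stop codon from the CDS should be aware distances to the
stop codon shift by 3 nt).

Assumptions the method inherits:

* the annotation's start codons are correct — misannotated TISs
  contaminate the profiles;
* an initiation peak exists — libraries depleted of initiating
  ribosomes (e.g. run-off elongation protocols) weaken the anchor;
* offsets depend on read length but not on transcript identity.

## The two-step estimation

**Profiles.** For each read length L, reads spanning a TIS
(`end5 ≤ s ≤ end3`, coding transcripts with a non-empty 5′ UTR)
contribute their 5′ end at `x = end5 − s` and 3′ end at
`x = end3 − s` to the (L, extremity) profile.

**Temporary offsets.** The 5′ temporary offset is `−x` at the global
maximum of the 5′ profile over `x ∈ [−L+FL, −FL]`; the 3′ offset is
the `x` of the 3′-profile maximum over `x ∈ [FL−1, L−FL−1]`. The
flanking length FL (default 9 nt) excludes extremities so close to
the start codon that they cannot belong to an initiating footprint;
the asymmetric `FL−1` on the 3′ side mirrors the fact that a 3′ end
exactly FL−1 nt downstream of the TIS is still geometrically
admissible. Ties at the maximum break toward the smallest offset
magnitude. Windows with no signal leave the offset undefined and the
bin falls through to the correction fallback.

**Optimal offset.** Each extremity's temporary offsets are expanded
into multisets weighted by the number of TIS-spanning reads per
length; the mode of the extremity with the higher mode-frequency is
the optimal offset (oPO), with the 5′ side winning exact ties and
within-extremity mode ties breaking toward the smaller offset. This
lets the abundant, well-behaved length bins lend their consensus to
sparse ones.

**Correction.** Per length bin, on the optimal extremity: a temporary
offset equal to the oPO stands. Otherwise the candidates are the
local maxima of that bin's profile inside the temporary-offset search
window, converted to offsets, and the candidate minimizing
`|candidate − oPO|` wins. The minimization is over the *absolute*
difference: a signed minimum would always select the leftmost
maximum, which contradicts the worked corrections the method was
validated against (e.g. a 31-nt bin with temporary 3′ offset 19 and
local maxima at offsets 19 and 17 corrects to 17, not 19). Distance
ties break toward the temporary offset, then toward the smaller
offset. A discrete local maximum is a run of equal positive values
strictly greater than both outer neighbours; a window boundary counts
against its single inner neighbour; a plateau reports its first
position. Bins with no candidates — including lengths never observed
at a TIS — take the oPO itself, so every read in the dataset can be
assigned a P-site. The opposite extremity's offset is always derived
as `L − 1 − cPO`, which makes the complementarity identity
`cpo5 + cpo3 = L − 1` structural rather than empirical.

The local-maxima search is confined to the same window used for the
temporary offset, keeping the corrected estimate comparable to the
temporary one; nothing outside the window can become a candidate.

## Length selection

Three modes: keep all lengths; keep a user list; or keep lengths
passing a periodicity threshold (default 50%). The threshold is
evaluated as the maximum over the three frames of the fraction of a
length's reads whose 5′ end lies inside a CDS, frame
`(end5 − s) mod 3`. This statistic is invariant under shifting all
reads of a bin by a constant, so it is well-defined *before* offsets
are known — the property that makes pre-offset filtering coherent.
Lengths exactly at the threshold are kept. Whether periodicity should
instead be assessed on codon-anchored windows is left open; the
report table exposes the per-length max-frame fractions so users can
audit the decision.

## P-site annotation and diagnostics

`psite = end5 + cpo5(L)`; reads whose P-site falls outside `[1, l_tr]`
are dropped with a logged count, as are reads on transcripts missing
from the annotation or lacking a CDS (region and frame are undefined
without one; such transcripts still count in the length
distribution). `psite_from_stop` is measured to the *first*
nucleotide of the stop codon (`e − 2`), so 0 means "P-site on the
stop codon". Frame is the non-negative `psite_from_start mod 3` in
all three regions — frame composition of the UTRs is itself a
diagnostic.

The expected region occupancy contrasts observed P-site percentages
with region lengths summed over the transcripts carrying at least one
P-site, unweighted by read abundance: the comparison is against
sequence composition, not expression. The codon usage index is the
share of in-frame CDS P-sites per codon divided by that codon's
frequency among the CDS codons of the covered transcripts; the
codon-frequency-weighted mean of the index is 1 by construction, and
the index is reported as a raw ratio without rescaling. The TIS
accuracy score uses the P-site metagene profile aggregated over all
retained lengths; its numerator runs over in-frame positions
`{0, 3, 6, 9, 12}` and its denominator over `{−15, −12, …, 12}`.
The default metagene window is 25 nt each side of the anchor
(configurable; the score only needs `[−15, 14]`).

## Synthetic data

The generator emulates a mammalian-style monosome library on a
transcriptome of (by default) 200 transcripts with 60–200 nt 5′ UTRs,
300–1200 nt CDSs (multiples of 3, ATG…TAA) and 50–250 nt 3′ UTRs.
Read lengths 26–32 nt peak at 28–29; the true offset map is
{26: 9, 27: 10, 28: 11, 29: 12, 30: 12, 31: 13, 32: 15}, drifting
with length as real offset tables do. A read's P-site is drawn in
three tiers: off-CDS (UTR-uniform) with probability `noise` (default
0.02); otherwise on the start codon with probability `tis_fraction`
(default 0.10 — a realistic share for the initiation peak of standard
cycloheximide libraries); otherwise a uniform in-frame CDS codon,
knocked out of frame by +1/+2 with probability `1 − periodicity`
(default 0.95 in frame). Extremities follow from the true offsets
(`end5 = psite − o(L)`); out-of-bounds reads are rejected and redrawn.
All draws flow through one `numpy` generator keyed by the seed, and
BAM emission uses ungapped `{L}M` CIGARs so parsing round-trips
losslessly.

What the simulation does *not* model: nuclease sequence bias, ligation
bias, uneven transcript expression, multi-mapping across isoforms,
misannotated or alternative TISs, uORF translation, and offset spread
*within* a length bin. Passing the recovery tests therefore shows the
estimator is correct under its own assumptions — exact recovery of
every generating offset at 50,000 reads — not that it is robust to
every artefact of real libraries. Offsets on real data should always
be sanity-checked against the end heatmaps.

## Numerical and design choices

* All tie-breaks are deterministic and documented above; the core has
  no randomness.
* Offsets are estimated per sample independently; `pool_samples`
  merges TIS profiles before estimation for shallow replicates.
* Table outputs are the CLI contract; plots are best-effort renderings
  of the same tables and are excluded from tests.
* Problem sizes in the test suite (60–200 transcripts, 10⁴–5·10⁴
  reads) are the smallest at which every length bin keeps ≥ 50
  TIS-spanning reads, the coverage at which exact recovery is the
  designed behaviour.

## Known limitations

* Genome-space BAMs are not lifted to transcript space; align to the
  transcriptome first.
* Sequences must be supplied as transcript FASTA; no genome-build
  retrieval.
* Offset estimation anchored on stop codons or ORF-internal
  periodicity is out of scope.
* Non-coding transcripts receive no P-site records (no CDS, no frame).
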