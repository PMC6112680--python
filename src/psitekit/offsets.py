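"""Two-step P-site offset estimation anchored on translation initiation.

The P-site offset (PO) of a footprint is the distance between one of
its extremities and the first nucleotide of the P-site codon. Ribosomes
caught in initiation hold the start codon in their P-site, so reads
spanning an annotated translation initiation site (TIS) reveal the
offset directly: for each read length L, the occupancy profile of read
extremities around the TIS peaks at the position the extremity keeps
from the P-site.

Estimation proceeds in two steps.

1. *Temporary offsets* (tPO). For each length bin, take the global
   maximum of the 5' end profile over ``x ∈ [-L+FL, -FL]`` and of the
   3' end profile over ``x ∈ [FL-1, L-FL-1]``, where ``x`` is the
   position relative to the TIS and FL (flanking length, default 9 nt)
   keeps extremities too close to the start codon out of the search.
   The 5' offset is the (positive) distance ``-x`` of that maximum;
   the 3' offset is ``x`` itself.

2. *Correction* (cPO). Sparse length bins produce erratic temporary
   offsets. A global reference — the optimal offset (oPO) — is the
   most frequent temporary offset across reads: each extremity's tPOs
   are expanded into read-weighted multisets and the mode of the more
   frequent extremity wins (5' on ties). Bins whose temporary offset
   on the winning extremity already equals the oPO are untouched;
   otherwise the corrected offset is the local maximum of that bin's
   profile whose offset lies closest to the oPO. Bins with no usable
   signal fall back to the oPO itself, so every read length in the
   dataset receives an offset.

The offset from the other extremity always follows from
``cpo5 + cpo3 = L - 1``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .annotation import cds_start

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


class OffsetEstimationError(ValueError):
    """Raised when offsets cannot be estimated from the given reads."""


@dataclass
class TisProfileSet:
    """Per-length occupancy profiles of read extremities around the TIS.

    ``counts[(L, extremity)]`` maps ``x`` (position relative to the
    TIS; ``x = pos - s``, TIS at ``x = 0``) to the number of read ends
    observed there, over reads of length ``L`` spanning the TIS.
    """

    flanking: int = 9
    counts: dict[tuple[int, str], Counter] = field(default_factory=dict)
    n_tis_reads: dict[int, int] = field(default_factory=dict)

    def profile(self, length: int, extremity: str) -> Counter:
        return self.counts.get((length, extremity), Counter())

    def lengths(self) -> list[int]:
        return sorted(self.n_tis_reads)


def build_tis_profiles(
    reads: pd.DataFrame, annotation: pd.DataFrame, flanking: int = 9
) -> TisProfileSet:
    """Tally 5' and 3' read ends around start codons, per read length.

    A read contributes iff it spans the TIS (``end5 <= s <= end3``) of
    a coding transcript with a non-empty 5' UTR; its 5' end increments
    the (L, 5') profile at ``x = end5 - s`` and its 3' end the (L, 3')
    profile at ``x = end3 - s``.
    """
    coding = annotation[(annotation["l_cds"] > 0) & (annotation["l_utr5"] > 0)].copy()
    coding["s"] = cds_start(coding)
    merged = reads.merge(coding[["transcript", "s"]], on="transcript", how="inner")
    spanning = merged[(merged["end5"] <= merged["s"]) & (merged["s"] <= merged["end3"])]
    if len(spanning) == 0:
        raise OffsetEstimationError(
            "no reads span a translation initiation site: cannot estimate offsets"
        )
    profiles = TisProfileSet(flanking=flanking)
    x5 = spanning["end5"] - spanning["s"]
    x3 = spanning["end3"] - spanning["s"]
    for length, grp in spanning.groupby("length"):
        length = int(length)
        profiles.counts[(length, FIVE_PRIME)] = Counter(x5.loc[grp.index].tolist())
        profiles.counts[(length, THREE_PRIME)] = Counter(x3.loc[grp.index].tolist())
        profiles.n_tis_reads[length] = len(grp)
    return profiles


def _argmax_offset(profile: Counter, window: range, to_offset) -> int | None:
    """Offset of the global maximum of ``profile`` over ``window``.

    Ties are broken toward the smallest offset magnitude. Returns None
    when the window holds no signal.
    """
    best = None
    for x in window:
        count = profile.get(x, 0)
        if count == 0:
            continue
        offset = to_offset(x)
        if (
            best is None
            or count > best[0]
            or (count == best[0] and abs(offset) < abs(best[1]))
        ):
            best = (count, offset)
    return None if best is None else best[1]


def temporary_offsets(
    profiles: TisProfileSet, length: int, flanking: int | None = None
) -> tuple[int | None, int | None]:
    """Temporary 5' and 3' offsets for one length bin.

    The 5' offset is ``-x`` of the 5'-profile maximum over
    ``[-L+FL, -FL]``; the 3' offset is the ``x`` of the 3'-profile
    maximum over ``[FL-1, L-FL-1]``. Either is None when its window
    holds no read ends.
    """
    fl = profiles.flanking if flanking is None else flanking
    tpo5 = _argmax_offset(
        profiles.profile(length, FIVE_PRIME),
        range(-length + fl, -fl + 1),
        lambda x: -x,
    )
    tpo3 = _argmax_offset(
        profiles.profile(length, THREE_PRIME),
        range(fl - 1, length - fl),
        lambda x: x,
    )
    return tpo5, tpo3


def optimal_offset(
    tpos: dict[int, tuple[int | None, int | None]],
    weights: dict[int, float],
) -> tuple[int, str]:
    """Global optimal offset: the most frequent read-level temporary offset.

    Each extremity's per-length temporary offsets are expanded into
    multisets weighted by the number of TIS-spanning reads per length
    (any non-negative weights work, e.g. read percentages); the mode of
    the extremity with the higher frequency wins, the 5' side on ties.
    Mode ties within one extremity are broken toward the smaller offset.

    Returns ``(opo, extremity)`` with extremity in
    ``{"five_prime", "three_prime"}``.
    """
    freq5: Counter = Counter()
    freq3: Counter = Counter()
    for length, (tpo5, tpo3) in tpos.items():
        w = weights.get(length, 0)
        if w <= 0:
            continue
        if tpo5 is not None:
            freq5[tpo5] += w
        if tpo3 is not None:
            freq3[tpo3] += w

    def _mode(freq: Counter) -> tuple[int, float] | None:
        if not freq:
            return None
        best_w = max(freq.values())
        best = min(o for o, w in freq.items() if w == best_w)
        return best, best_w

    mode5 = _mode(freq5)
    mode3 = _mode(freq3)
    if mode5 is None and mode3 is None:
        raise OffsetEstimationError(
            "no defined temporary offsets with positive weight"
        )
    if mode3 is None or (mode5 is not None and mode5[1] >= mode3[1]):
        return mode5[0], FIVE_PRIME
    return mode3[0], THREE_PRIME


def local_maxima(profile: Counter, window: range) -> list[int]:
    """Positions of local maxima of a discrete profile within a window.

    A run of equal positive values is a local maximum when both of its
    outer neighbours within the window are strictly smaller (a window
    boundary counts as a maximum against its single inner neighbour);
    the run's first position is reported.
    """
    xs = list(window)
    if not xs:
        return []
    values = [profile.get(x, 0) for x in xs]
    maxima = []
    i = 0
    n = len(xs)
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if values[i] > 0:
            left_ok = i == 0 or values[i - 1] < values[i]
            right_ok = j == n - 1 or values[j + 1] < values[i]
            if left_ok and right_ok:
                maxima.append(xs[i])
        i = j + 1
    return maxima


def correct_offsets(
    profiles: TisProfileSet,
    tpos_optimal: dict[int, int | None],
    opo: int,
    extremity: str,
    flanking: int | None = None,
) -> dict[int, tuple[int, int]]:
    """Correct per-length offsets against the optimal offset.

    ``tpos_optimal`` maps each read length of the dataset to its
    temporary offset on the optimal extremity (None when undefined).
    For each length: an offset equal to the oPO stands; otherwise the
    candidate offsets are the local maxima of the bin's profile on the
    optimal extremity within the temporary-offset search window, and
    the one closest to the oPO wins (ties broken toward the temporary
    offset, then toward the smaller offset). Bins with no candidates
    fall back to the oPO itself.

    Returns ``{L: (cpo5, cpo3)}`` with ``cpo5 + cpo3 = L - 1``.
    """
    fl = profiles.flanking if flanking is None else flanking
    corrected: dict[int, tuple[int, int]] = {}
    for length, tpo in tpos_optimal.items():
        if tpo is None:
            cpo = opo
            logger.debug("length %d: no temporary offset, falling back to oPO", length)
        elif tpo == opo:
            cpo = tpo
        else:
            if extremity == FIVE_PRIME:
                window = range(-length + fl, -fl + 1)
                candidates = [-x for x in local_maxima(profiles.profile(length, FIVE_PRIME), window)]
            else:
                window = range(fl - 1, length - fl)
                candidates = list(local_maxima(profiles.profile(length, THREE_PRIME), window))
            if not candidates:
                cpo = opo
            else:
                cpo = min(
                    candidates, key=lambda c: (abs(c - opo), abs(c - tpo), c)
                )
        if extremity == FIVE_PRIME:
            corrected[length] = (cpo, length - 1 - cpo)
        else:
            corrected[length] = (length - 1 - cpo, cpo)
    return corrected


OFFSET_COLUMNS = [
    "sample",
    "length",
    "n_tis_reads",
    "pct_tis_reads",
    "pct_all_reads",
    "tpo5",
    "tpo3",
    "cpo5",
    "cpo3",
    "opo",
    "opo_extremity",
]


def _offsets_single_sample(
    reads: pd.DataFrame, annotation: pd.DataFrame, flanking: int, sample: str
) -> pd.DataFrame:
    profiles = build_tis_profiles(reads, annotation, flanking=flanking)
    all_lengths = sorted(int(length) for length in reads["length"].unique())
    tpos = {length: temporary_offsets(profiles, length) for length in profiles.lengths()}
    opo, extremity = optimal_offset(
        tpos, {length: profiles.n_tis_reads[length] for length in tpos}
    )
    idx = 0 if extremity == FIVE_PRIME else 1
    tpos_optimal = {length: (tpos.get(length) or (None, None))[idx] for length in all_lengths}
    corrected = correct_offsets(profiles, tpos_optimal, opo, extremity)

    n_tis_total = sum(profiles.n_tis_reads.values())
    length_counts = reads["length"].value_counts()
    rows = []
    for length in all_lengths:
        n_tis = profiles.n_tis_reads.get(length, 0)
        tpo5, tpo3 = tpos.get(length, (None, None))
        cpo5, cpo3 = corrected[length]
        rows.append(
            {
                "sample": sample,
                "length": length,
                "n_tis_reads": n_tis,
                "pct_tis_reads": 100.0 * n_tis / n_tis_total,
                "pct_all_reads": 100.0 * int(length_counts.get(length, 0)) / len(reads),
                "tpo5": tpo5,
                "tpo3": tpo3,
                "cpo5": cpo5,
                "cpo3": cpo3,
                "opo": opo,
                "opo_extremity": extremity,
            }
        )
    out = pd.DataFrame(rows, columns=OFFSET_COLUMNS)
    out["tpo5"] = out["tpo5"].astype("Int64")
    out["tpo3"] = out["tpo3"].astype("Int64")
    return out


def compute_psite_offsets(
    reads: pd.DataFrame,
    annotation: pd.DataFrame,
    flanking: int = 9,
    pool_samples: bool = False,
) -> pd.DataFrame:
    """Run the full two-step offset estimation on a read table.

    With multiple samples present, offsets are estimated per sample
    independently unless ``pool_samples`` is set, in which case the TIS
    profiles of all samples are merged into a single estimation (rows
    are then labelled ``pooled``).

    Returns the per-length offset table with columns
    ``sample, length, n_tis_reads, pct_tis_reads, pct_all_reads,
    tpo5, tpo3, cpo5, cpo3, opo, opo_extremity``.
    """
    samples = reads["sample"].unique() if "sample" in reads.columns else ["sample"]
    if pool_samples or len(samples) <= 1:
        label = samples[0] if len(samples) == 1 else "pooled"
        return _offsets_single_sample(reads, annotation, flanking, str(label))
    tables = [
        _offsets_single_sample(
            reads[reads["sample"] == sample], annotation, flanking, str(sample)
        )
        for sample in samples
    ]
    return pd.concat(tables, ignore_index=True)
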