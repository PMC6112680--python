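"""Diagnostic statistics for P-site-annotated ribosome profiling data.

These summaries answer the questions a practitioner asks after offset
estimation: is the signal enriched in coding regions, does it step in
trinucleotide frame, do the read extremities line up with the start
and stop codons, and which codons carry the most ribosome density.

Two scalar quality scores summarise the positioning:

* *Periodicity score* — the percentage of CDS P-sites falling in
  frame 0; the higher, the cleaner the periodicity.
* *TIS accuracy score* — on the start-anchored metagene profile
  ``f(x)``, the ratio of in-frame signal just downstream of the start
  codon to in-frame signal in a window spanning it symmetrically::

      sum over x in {0, 3, ..., 12} of f(x)
      --------------------------------------
      sum over x in {-15, -12, ..., 12} of f(x)

  A score of 1 means periodic signal exists only inside the CDS; lower
  scores flag spurious periodicity in the 5' UTR, the signature of a
  misestimated offset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .annotation import cds_start, cds_stop

logger = logging.getLogger(__name__)

REGIONS = ["utr5", "cds", "utr3"]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class MetaProfile:
    """Metagene profile: P-site counts by position relative to an anchor.

    ``anchor`` is ``"start"`` (x = 0 at the first nucleotide of the
    start codon) or ``"stop"`` (x = 0 at the first nucleotide of the
    stop codon). ``counts`` is indexed by x over the full requested
    window, zeros included.
    """

    anchor: str
    counts: pd.Series
    window: tuple[int, int]


def region_psite_stats(psites: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Observed vs expected percentage of P-sites per transcript region.

    The expected distribution is uniform weighted on region lengths —
    the fingerprint of random positioning — computed over the
    transcripts that carry at least one P-site.
    """
    if len(psites) == 0:
        raise ValueError("no P-sites to summarise")
    observed = psites["region"].value_counts()
    covered = annotation[annotation["transcript"].isin(psites["transcript"].unique())]
    region_lengths = {
        "utr5": covered["l_utr5"].sum(),
        "cds": covered["l_cds"].sum(),
        "utr3": covered["l_utr3"].sum(),
    }
    total_len = sum(region_lengths.values())
    return pd.DataFrame(
        {
            "region": REGIONS,
            "observed_pct": [
                100.0 * observed.get(r, 0) / len(psites) for r in REGIONS
            ],
            "expected_pct": [
                100.0 * region_lengths[r] / total_len for r in REGIONS
            ],
        }
    )


def frame_stats(psites: pd.DataFrame, by_length: bool = False) -> pd.DataFrame:
    """Percentage of P-sites per reading frame, by region (and length).

    Within each region (or region × length stratum) the three frame
    percentages sum to 100.
    """
    keys = ["region", "length"] if by_length else ["region"]
    rows = []
    for group_key, grp in psites.groupby(keys):
        if not isinstance(group_key, tuple):
            group_key = (group_key,)
        frames = grp["frame"].value_counts()
        for frame in (0, 1, 2):
            rows.append(
                dict(
                    zip(keys, group_key),
                    frame=frame,
                    pct=100.0 * frames.get(frame, 0) / len(grp),
                )
            )
    return pd.DataFrame(rows)


def _anchor_positions(annotation: pd.DataFrame, anchor: str) -> pd.DataFrame:
    coding = annotation[annotation["l_cds"] > 0].copy()
    if anchor == "start":
        coding["anchor_pos"] = cds_start(coding)
    elif anchor == "stop":
        coding["anchor_pos"] = cds_stop(coding) - 2
    else:
        raise ValueError("anchor must be 'start' or 'stop'")
    return coding[["transcript", "anchor_pos"]]


def metagene_profile(
    psites: pd.DataFrame,
    annotation: pd.DataFrame,
    anchor: str = "start",
    window: tuple[int, int] = (-25, 25),
) -> MetaProfile:
    """Aggregate P-site counts over transcripts relative to an anchor.

    ``f(x)`` = number of P-sites at distance x from the anchor's first
    nucleotide (start codon or stop codon), summed over transcripts.
    """
    anchors = _anchor_positions(annotation, anchor)
    merged = psites.merge(anchors, on="transcript", how="inner")
    x = merged["psite"] - merged["anchor_pos"]
    lo, hi = window
    counts = x[(x >= lo) & (x <= hi)].value_counts()
    full = counts.reindex(range(lo, hi + 1), fill_value=0).astype(int)
    full.index.name = "x"
    return MetaProfile(anchor=anchor, counts=full, window=window)


def ends_heatmap_data(
    reads: pd.DataFrame,
    annotation: pd.DataFrame,
    window: tuple[int, int] = (-25, 25),
) -> pd.DataFrame:
    """Per-length counts of read 5'/3' ends around the start and stop codons.

    Source data for the metagene end heatmaps used to eyeball offset
    reliability. Returns a long table with columns
    ``length, extremity, anchor, x, count``.
    """
    lo, hi = window
    rows = []
    for anchor in ("start", "stop"):
        anchors = _anchor_positions(annotation, anchor)
        merged = reads.merge(anchors, on="transcript", how="inner")
        for extremity, col in (("five_prime", "end5"), ("three_prime", "end3")):
            x = merged[col] - merged["anchor_pos"]
            sub = merged[(x >= lo) & (x <= hi)].copy()
            sub["x"] = x[(x >= lo) & (x <= hi)]
            tallies = sub.groupby(["length", "x"]).size()
            for (length, pos), count in tallies.items():
                rows.append(
                    {
                        "length": int(length),
                        "extremity": extremity,
                        "anchor": anchor,
                        "x": int(pos),
                        "count": int(count),
                    }
                )
    return pd.DataFrame(rows, columns=["length", "extremity", "anchor", "x", "count"])


def codon_usage(
    psites: pd.DataFrame,
    sequences: dict[str, str],
    annotation: pd.DataFrame,
    include_stop_codons: bool = True,
) -> pd.DataFrame:
    """Codon usage index from in-frame CDS P-sites.

    For each codon c, ``usage_index(c)`` is the share of in-frame CDS
    P-sites landing on c divided by the frequency of c among the CDS
    codons of the transcripts carrying at least one in-frame CDS
    P-site. An index of 1 means ribosome density proportional to codon
    abundance; higher values mark codons where ribosomes dwell.

    Codons never occurring in the covered coding sequences are
    excluded. The codon-frequency-weighted mean of the index is 1 by
    construction.
    """
    inframe = psites[(psites["region"] == "cds") & (psites["frame"] == 0)]
    if len(inframe) == 0:
        raise ValueError("no in-frame CDS P-sites: cannot compute codon usage")
    if "codon" in inframe.columns:
        psite_codons = inframe["codon"].dropna()
    else:
        raise ValueError("P-site table lacks codons; pass sequences to assign_psites")

    coding = annotation[annotation["l_cds"] > 0].copy()
    coding["s"] = cds_start(coding)
    coding["e"] = cds_stop(coding)
    covered = coding[coding["transcript"].isin(inframe["transcript"].unique())]
    codon_counts: dict[str, int] = {}
    for tx, s, e in zip(covered["transcript"], covered["s"], covered["e"]):
        seq = sequences.get(tx)
        if seq is None:
            continue
        for pos in range(s - 1, e - 2, 3):
            codon = seq[pos : pos + 3]
            codon_counts[codon] = codon_counts.get(codon, 0) + 1
    if not include_stop_codons:
        codon_counts = {
            c: n for c, n in codon_counts.items() if c not in STOP_CODONS
        }
        psite_codons = psite_codons[~psite_codons.isin(STOP_CODONS)]
    total_codons = sum(codon_counts.values())
    psite_tally = psite_codons.value_counts()
    n_psites = int(psite_tally.sum())

    rows = []
    for codon in sorted(codon_counts):
        freq = codon_counts[codon] / total_codons
        count = int(psite_tally.get(codon, 0))
        rows.append(
            {
                "codon": codon,
                "psite_count": count,
                "codon_freq": freq,
                "usage_index": (count / n_psites) / freq,
            }
        )
    return pd.DataFrame(rows)


def periodicity_score(psites: pd.DataFrame) -> float:
    """Percentage of CDS P-sites in frame 0."""
    cds = psites[psites["region"] == "cds"]
    if len(cds) == 0:
        raise ValueError("no CDS P-sites: periodicity score undefined")
    return 100.0 * (cds["frame"] == 0).sum() / len(cds)


def tis_accuracy_score(meta: MetaProfile | pd.Series) -> float:
    """In-frame metagene signal downstream of the TIS over the full window.

    Ratio of f summed over in-frame positions x in [0, 14] to f summed
    over in-frame positions x in [-15, 14], on a start-anchored
    metagene profile. Returns NaN when the denominator is zero.
    """
    counts = meta.counts if isinstance(meta, MetaProfile) else meta
    if isinstance(meta, MetaProfile) and meta.anchor != "start":
        raise ValueError("TIS accuracy score requires a start-anchored profile")
    present = set(counts.index)
    required = {x for x in range(-15, 15) if x % 3 == 0}
    if not required <= present:
        raise ValueError("metagene window must cover [-15, 14]")
    numerator = sum(counts.loc[x] for x in range(0, 15, 3))
    denominator = sum(counts.loc[x] for x in range(-15, 15, 3))
    if denominator == 0:
        logger.warning("TIS accuracy score undefined: no in-frame signal in window")
        return math.nan
    return float(numerator / denominator)


def transcript_profile(
    psites: pd.DataFrame,
    transcript_id: str,
    samples: list[str] | None = None,
    scale_factors: dict[str, float] | None = None,
    lengths: list[int] | None = None,
    l_tr: int | None = None,
) -> pd.Series:
    """Per-nucleotide P-site coverage along one transcript.

    Replicates are combined as ``sum_s scale_s * counts_s`` (default
    scale 1 per sample). ``lengths`` restricts to a subset of read
    lengths; ``l_tr`` extends the index to the full transcript.
    """
    sub = psites[psites["transcript"] == transcript_id]
    if samples is not None:
        sub = sub[sub["sample"].isin(samples)]
    if lengths is not None:
        sub = sub[sub["length"].isin(lengths)]
    scale_factors = scale_factors or {}
    coverage: pd.Series | None = None
    for sample, grp in sub.groupby("sample"):
        scaled = grp["psite"].value_counts().sort_index() * scale_factors.get(sample, 1.0)
        coverage = scaled if coverage is None else coverage.add(scaled, fill_value=0.0)
    if coverage is None:
        coverage = pd.Series(dtype=float)
    if l_tr is not None:
        coverage = coverage.reindex(range(1, l_tr + 1), fill_value=0.0)
    coverage.index.name = "position"
    return coverage.rename("coverage")
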