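"""P-site assignment: apply per-length offsets to every read.

Once per-length corrected offsets exist, the P-site of a read is fully
determined: ``psite = end5 + cpo5(L) = end3 - cpo3(L)`` (first
nucleotide of the P-site codon, transcript coordinates). Each read is
annotated with its distance from the start and stop codons, the
transcript region holding the P-site, the reading frame, and — when
transcript sequences are available — the codon under the P-site.

Conventions:

* ``psite_from_start = psite - s``: 0 means the P-site sits on the
  start codon.
* ``psite_from_stop = psite - (e - 2)``: 0 means the P-site sits on
  the stop codon (distance to the stop codon's first nucleotide).
* ``frame = psite_from_start mod 3``, non-negative, defined in all
  three regions.
"""

from __future__ import annotations

import logging

import pandas as pd

from .annotation import cds_start, cds_stop

logger = logging.getLogger(__name__)

PSITE_COLUMNS = [
    "sample",
    "transcript",
    "end5",
    "end3",
    "length",
    "psite",
    "psite_from_start",
    "psite_from_stop",
    "region",
    "frame",
]


def assign_psites(
    reads: pd.DataFrame,
    offsets: pd.DataFrame,
    annotation: pd.DataFrame,
    sequences: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate every read with its P-site position and derived fields.

    Parameters
    ----------
    reads
        Read table (``sample, transcript, end5, end3, length``).
    offsets
        Per-length offset table from
        :func:`psitekit.offsets.compute_psite_offsets`. When it carries
        several samples, offsets are joined per ``(sample, length)``.
    annotation
        Transcript annotation; reads on transcripts missing from it, or
        on non-coding transcripts (no CDS, hence no frame or region),
        are dropped with a logged count.
    sequences
        Optional transcript sequences; adds a ``codon`` column with the
        3-mer starting at the P-site where it fits in the transcript.

    Returns
    -------
    pandas.DataFrame
        One row per read whose P-site lies within ``[1, l_tr]``.
    """
    offset_cols = ["length", "cpo5", "cpo3"]
    if "sample" in offsets.columns and offsets["sample"].nunique() > 1:
        merged = reads.merge(offsets[["sample"] + offset_cols], on=["sample", "length"])
    else:
        merged = reads.merge(offsets[offset_cols].drop_duplicates("length"), on="length")

    n_in = len(merged)
    coding = annotation[annotation["l_cds"] > 0].copy()
    coding["s"] = cds_start(coding)
    coding["e"] = cds_stop(coding)
    merged = merged.merge(
        coding[["transcript", "l_tr", "s", "e"]], on="transcript", how="inner"
    )
    n_dropped_tx = n_in - len(merged)
    if n_dropped_tx:
        logger.warning(
            "%d read(s) dropped: transcript missing from annotation or non-coding",
            n_dropped_tx,
        )

    merged["psite"] = merged["end5"] + merged["cpo5"]
    inside = (merged["psite"] >= 1) & (merged["psite"] <= merged["l_tr"])
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("%d read(s) dropped: P-site outside the transcript", n_outside)
    merged = merged[inside].copy()

    # two routes to the same position; guaranteed by cpo5 + cpo3 = L - 1
    assert (merged["end5"] + merged["cpo5"] == merged["end3"] - merged["cpo3"]).all()

    merged["psite_from_start"] = merged["psite"] - merged["s"]
    merged["psite_from_stop"] = merged["psite"] - (merged["e"] - 2)
    merged["region"] = "cds"
    merged.loc[merged["psite"] < merged["s"], "region"] = "utr5"
    merged.loc[merged["psite"] > merged["e"], "region"] = "utr3"
    merged["frame"] = merged["psite_from_start"] % 3

    out = merged[PSITE_COLUMNS].reset_index(drop=True)
    if sequences is not None:
        l_tr = merged["l_tr"].reset_index(drop=True)
        out["codon"] = [
            sequences[tx][p - 1 : p + 2]
            if tx in sequences and p + 2 <= lt
            else None
            for tx, p, lt in zip(out["transcript"], out["psite"], l_tr)
        ]
    return out


def cds_psite_counts(
    psites: pd.DataFrame, annotation: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-transcript counts of in-frame P-sites within the CDS.

    A proxy for transcript-specific translation levels. When
    ``annotation`` is given, transcripts without any in-frame CDS
    P-site are included with a count of zero.
    """
    inframe = psites[(psites["region"] == "cds") & (psites["frame"] == 0)]
    counts = inframe.groupby("transcript").size()
    if annotation is not None:
        counts = counts.reindex(annotation["transcript"], fill_value=0)
    return (
        counts.rename("n_inframe_cds_psites")
        .reset_index()
        .rename(columns={"index": "transcript"})
    )
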