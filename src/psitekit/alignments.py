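"""Transcriptome-space BAM parsing into read alignment tables.

Reads are ribosome protected fragments aligned to transcript
references. Each retained alignment becomes one row with the 1-based
positions of its aligned extremities:

* ``end5`` — leftmost aligned base (soft/hard clips excluded),
* ``end3`` — rightmost aligned base,
* ``length`` — aligned reference span, ``end3 - end5 + 1``.

"Read length" is therefore the span on the transcript after clipping,
not the raw sequence length: P-site offsets are defined on aligned
extremities, so the extremities must be the aligned ones. Deletions and
other reference-consuming CIGAR operations extend the span accordingly.

Retained alignments are mapped, primary, non-supplementary and on the
forward strand (transcriptome alignments are sense-strand by
construction; a reverse-strand record cannot be a footprint of a
translating ribosome on that transcript).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

READ_COLUMNS = ["sample", "transcript", "end5", "end3", "length"]


class AlignmentError(ValueError):
    """Raised when an alignment file yields no usable reads."""


def load_alignments(
    path: str | Path,
    sample: str | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Parse a transcriptome BAM/SAM file into a read table.

    Parameters
    ----------
    path
        BAM (or SAM) file whose references are transcript ids.
    sample
        Sample label stored in the ``sample`` column; defaults to the
        file stem.
    annotation
        When given, reads aligned to transcripts absent from the
        annotation are kept but flagged in an ``in_annotation`` column.

    Returns
    -------
    pandas.DataFrame
        Columns ``sample, transcript, end5, end3, length`` (one row per
        retained alignment).

    Raises
    ------
    AlignmentError
        If no alignment passes the filters (e.g. fully unmapped file).
    """
    path = Path(path)
    sample = sample if sample is not None else path.stem
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    rows = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_reverse
            ):
                continue
            end5 = aln.reference_start + 1
            end3 = aln.reference_end  # 0-based exclusive == 1-based inclusive
            rows.append((sample, aln.reference_name, end5, end3, end3 - end5 + 1))
    if not rows:
        raise AlignmentError(f"no mapped forward-strand primary alignments in {path}")
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    if annotation is not None:
        known = set(annotation["transcript"])
        reads["in_annotation"] = reads["transcript"].isin(known)
        n_unknown = int((~reads["in_annotation"]).sum())
        if n_unknown:
            logger.warning(
                "%d read(s) aligned to transcripts absent from the annotation",
                n_unknown,
            )
    return reads


def length_distribution(reads: pd.DataFrame) -> pd.DataFrame:
    """Per-length read counts and percentages (percentages sum to 100)."""
    if len(reads) == 0:
        raise AlignmentError("cannot compute a length distribution of zero reads")
    counts = reads["length"].value_counts().sort_index()
    return pd.DataFrame(
        {
            "length": counts.index,
            "count": counts.to_numpy(),
            "pct": 100.0 * counts.to_numpy() / len(reads),
        }
    ).reset_index(drop=True)


def write_bed(reads: pd.DataFrame, path: str | Path) -> None:
    """Export retained alignments as BED6 (0-based, half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": reads["transcript"],
            "start": reads["end5"] - 1,
            "end": reads["end3"],
            "name": reads["sample"],
            "score": 0,
            "strand": "+",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
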