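"""Transcript annotation: region lengths in transcript coordinates.

Every analysis downstream works in transcript (spliced) space, 1-based
and inclusive. A transcript is described by four lengths — total,
5' UTR, CDS and 3' UTR — from which the coding geometry follows:

* CDS start ``s = l_utr5 + 1`` (first nucleotide of the start codon,
  i.e. the translation initiation site, TIS),
* CDS end ``e = l_utr5 + l_cds`` (last nucleotide of the stop codon).

The stop codon is counted as part of the CDS: GTF ``stop_codon``
features, which by convention sit outside the ``CDS`` features, are
merged into the CDS span on load.

Annotation can come from a GTF/GFF3 file (region lengths are computed
by projecting exon/CDS intervals into spliced coordinates) or from a
minimal tab-separated table with columns
``transcript, l_tr, l_utr5, l_cds, l_utr3``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["transcript", "l_tr", "l_utr5", "l_cds", "l_utr3"]


class AnnotationError(ValueError):
    """Raised for unparseable or structurally invalid annotation input."""


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"gtf", "gff", "gff3"}:
        return "gff3" if suffix == "gff3" else suffix
    if suffix in {"tsv", "txt", "csv"}:
        return "tsv"
    raise AnnotationError(f"cannot infer annotation format from '{path.name}'")


def load_annotation(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Load transcript annotation from GTF/GFF3 or a minimal length table.

    Parameters
    ----------
    path
        Annotation file. For ``tsv``, a header row is required; the
        transcript column may be named ``transcript`` or ``transcript_id``.
    fmt
        One of ``gtf``, ``gff``, ``gff3``, ``tsv``; inferred from the
        file extension when omitted.

    Returns
    -------
    pandas.DataFrame
        One row per transcript with columns
        ``transcript, l_tr, l_utr5, l_cds, l_utr3``. Rows whose lengths
        do not satisfy ``l_tr = l_utr5 + l_cds + l_utr3`` (or with
        negative lengths) are dropped with a warning; the number of
        dropped rows is stored in ``df.attrs["n_dropped"]``.

    Raises
    ------
    AnnotationError
        On unparseable input or duplicated transcript identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    fmt = (fmt or _infer_format(path)).lower()
    if fmt == "tsv":
        df = _load_tsv(path)
    elif fmt in {"gtf", "gff", "gff3"}:
        df = _load_gxf(path)
    else:
        raise AnnotationError(f"unknown annotation format '{fmt}'")
    return _validate(df)


def _load_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise AnnotationError(f"unparseable annotation table {path}: {exc}") from exc
    df = df.rename(columns={"transcript_id": "transcript"})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(
            f"{path}: missing required columns {missing}; header must contain "
            f"{ANNOTATION_COLUMNS} (transcript_id accepted for transcript)"
        )
    df = df[ANNOTATION_COLUMNS].copy()
    for col in ANNOTATION_COLUMNS[1:]:
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise AnnotationError(
                f"{path}: non-integer value in column '{col}' (line {line})"
            ) from exc
    return df


def _feature_transcript_ids(feature) -> list[str]:
    attrs = feature.attributes
    if "transcript_id" in attrs:
        return list(attrs["transcript_id"])
    if "Parent" in attrs:
        return [p.split(":", 1)[-1] for p in attrs["Parent"]]
    return []


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _load_gxf(path: Path) -> pd.DataFrame:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise AnnotationError(f"unparseable GTF/GFF3 file {path}: {exc}") from exc

    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    strand: dict[str, str] = {}
    for feature in db.all_features():
        ftype = feature.featuretype.lower()
        if ftype not in {"exon", "cds", "stop_codon"}:
            continue
        for tid in _feature_transcript_ids(feature):
            strand[tid] = feature.strand
            if ftype == "exon":
                exons[tid].append((feature.start, feature.end))
            else:
                # stop_codon merged into the CDS span: the stop codon
                # is treated as coding throughout the package.
                cds[tid].append((feature.start, feature.end))

    rows = []
    for tid, exon_ivs in exons.items():
        exon_ivs = _merge_intervals(exon_ivs)
        l_tr = sum(e - s + 1 for s, e in exon_ivs)
        cds_ivs = _merge_intervals(cds.get(tid, []))
        if not cds_ivs:
            # non-coding transcript: retained with an empty CDS
            rows.append((tid, l_tr, 0, 0, l_tr))
            continue
        l_cds = sum(e - s + 1 for s, e in cds_ivs)
        cds_lo = cds_ivs[0][0]
        cds_hi = cds_ivs[-1][1]
        if strand.get(tid) == "-":
            upstream = sum(
                max(0, e - max(s, cds_hi + 1) + 1) for s, e in exon_ivs if e > cds_hi
            )
        else:
            upstream = sum(
                max(0, min(e, cds_lo - 1) - s + 1) for s, e in exon_ivs if s < cds_lo
            )
        rows.append((tid, l_tr, upstream, l_cds, l_tr - upstream - l_cds))
    if not rows:
        raise AnnotationError(f"no exon features with transcript ids found in {path}")
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    if df["transcript"].duplicated().any():
        dup = df.loc[df["transcript"].duplicated(), "transcript"].iloc[0]
        raise AnnotationError(f"duplicate transcript id '{dup}' in annotation")
    ok = (
        (df["l_tr"] == df["l_utr5"] + df["l_cds"] + df["l_utr3"])
        & (df[["l_utr5", "l_cds", "l_utr3"]] >= 0).all(axis=1)
        & (df["l_tr"] >= 1)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        bad = df.loc[~ok, "transcript"].tolist()
        logger.warning(
            "dropped %d transcript(s) violating l_tr = l_utr5 + l_cds + l_utr3: %s",
            n_dropped,
            ", ".join(map(str, bad[:5])) + ("..." if n_dropped > 5 else ""),
        )
    out = df.loc[ok].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write annotation as the minimal tab-separated length table."""
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def cds_start(annotation: pd.DataFrame) -> pd.Series:
    """1-based position of the first nucleotide of the start codon (s)."""
    return annotation["l_utr5"] + 1


def cds_stop(annotation: pd.DataFrame) -> pd.Series:
    """1-based position of the last nucleotide of the stop codon (e)."""
    return annotation["l_utr5"] + annotation["l_cds"]


def load_sequences(
    path: str | Path, annotation: pd.DataFrame | None = None
) -> dict[str, str]:
    """Load transcript sequences from FASTA, keyed by the header token.

    Sequences are uppercased. When ``annotation`` is given, transcripts
    whose sequence length disagrees with ``l_tr`` are dropped with a
    warning.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise AnnotationError(f"empty or unreadable FASTA file: {path}")
    if annotation is not None:
        expected = dict(zip(annotation["transcript"], annotation["l_tr"]))
        mismatched = [
            tid
            for tid, seq in sequences.items()
            if tid in expected and len(seq) != expected[tid]
        ]
        for tid in mismatched:
            logger.warning(
                "sequence length for %s (%d) != annotated l_tr (%d); dropped",
                tid,
                len(sequences[tid]),
                expected[tid],
            )
            del sequences[tid]
    return sequences
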