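"""Read-length selection before offset estimation.

Footprint length reflects ribosome conformation and nuclease
digestion, and not every length bin carries periodic signal. Three
selection modes are offered:

* ``all`` — keep every length (default);
* ``manual`` — keep only a user-supplied list of lengths;
* ``periodicity`` — keep a length only if its reads show enough frame
  bias: for each length, take the reads whose 5' end falls inside the
  CDS of a coding transcript, compute the frame ``(end5 - s) mod 3``,
  and keep the length iff the most populated frame holds at least
  ``threshold`` percent of those reads (default 50%).

The periodicity criterion deliberately uses raw 5' ends, not P-sites:
shifting all reads of a length bin by a constant offset permutes the
three frame counts, leaving the maximum unchanged, so the filter is
well-defined before any offset is known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotation import cds_start, cds_stop

logger = logging.getLogger(__name__)


@dataclass
class LengthFilterReport:
    """Audit record of a length-selection run."""

    mode: str
    kept_lengths: list[int]
    threshold: float | None = None
    max_frame_pct: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(set(self.kept_lengths) | set(self.max_frame_pct))
        return pd.DataFrame(
            {
                "length": lengths,
                "kept": [length in set(self.kept_lengths) for length in lengths],
                "max_frame_pct": [
                    self.max_frame_pct.get(length, float("nan")) for length in lengths
                ],
            }
        )


def filter_lengths(
    reads: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    mode: str = "all",
    lengths: list[int] | None = None,
    threshold: float = 50.0,
) -> tuple[pd.DataFrame, LengthFilterReport]:
    """Select which read lengths enter offset estimation.

    Returns the filtered read table and a :class:`LengthFilterReport`.
    """
    if mode == "all":
        kept = sorted(reads["length"].unique())
        return reads, LengthFilterReport(mode="all", kept_lengths=kept)

    if mode == "manual":
        if not lengths:
            raise ValueError("manual mode requires a non-empty list of lengths")
        keep = set(lengths)
        out = reads[reads["length"].isin(keep)]
        return out, LengthFilterReport(
            mode="manual", kept_lengths=sorted(out["length"].unique())
        )

    if mode == "periodicity":
        if not 0 < threshold <= 100:
            raise ValueError("periodicity threshold must be in (0, 100]")
        if annotation is None:
            raise ValueError("periodicity mode requires transcript annotation")
        coding = annotation[annotation["l_cds"] > 0].copy()
        coding["s"] = cds_start(coding)
        coding["e"] = cds_stop(coding)
        merged = reads.merge(
            coding[["transcript", "s", "e"]], on="transcript", how="inner"
        )
        in_cds = merged[(merged["end5"] >= merged["s"]) & (merged["end5"] <= merged["e"])]
        max_pct: dict[int, float] = {}
        kept_set: set[int] = set()
        for length in sorted(reads["length"].unique()):
            sub = in_cds[in_cds["length"] == length]
            if len(sub) == 0:
                logger.warning(
                    "length %d has no CDS-overlapping reads; dropped from selection",
                    length,
                )
                continue
            frames = ((sub["end5"] - sub["s"]) % 3).value_counts()
            pct = 100.0 * frames.max() / len(sub)
            max_pct[length] = pct
            if pct >= threshold:
                kept_set.add(length)
        out = reads[reads["length"].isin(kept_set)]
        return out, LengthFilterReport(
            mode="periodicity",
            kept_lengths=sorted(kept_set),
            threshold=threshold,
            max_frame_pct=max_pct,
        )

    raise ValueError(f"unknown length-selection mode '{mode}'")
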