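"""Synthetic transcriptomes and ribosome footprints with known offsets.

The generator produces the kind of data the offset algorithm assumes:
a transcriptome with annotated UTRs and CDSs, and reads whose P-site
is placed first and whose extremities follow from a known per-length
offset map ``o(L)`` (``end5 = psite - o(L)``). Because the truth is
the offset map itself, estimation can be validated by exact recovery.

A read's P-site is drawn in three tiers:

* with probability ``noise`` it lands uniformly in the UTRs
  (non-translating, off-CDS background);
* otherwise, with probability ``tis_fraction`` it sits exactly on the
  start codon (initiating ribosomes — the subpopulation the TIS
  anchoring exploits);
* otherwise it is a uniform in-frame CDS codon start, shifted out of
  frame by +1 or +2 with probability ``1 - periodicity``.

All randomness flows through one ``numpy`` generator keyed by
``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import READ_COLUMNS

BASES = np.array(list("ACGT"))

DEFAULT_LENGTH_PROBS = {
    26: 0.05,
    27: 0.15,
    28: 0.30,
    29: 0.25,
    30: 0.15,
    31: 0.07,
    32: 0.03,
}

DEFAULT_OFFSETS = {26: 9, 27: 10, 28: 11, 29: 12, 30: 12, 31: 13, 32: 15}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic footprint generator.

    Defaults model a mammalian-style monosome profiling library:
    footprints of 26-32 nt peaked at 28-29 nt, 5'-end offsets drifting
    from 9 to 15 nt with length, high but imperfect periodicity and a
    small off-CDS background.
    """

    n_transcripts: int = 200
    utr5_range: tuple[int, int] = (60, 200)
    cds_range: tuple[int, int] = (300, 1200)
    utr3_range: tuple[int, int] = (50, 250)
    length_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PROBS)
    )
    offsets: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    periodicity: float = 0.95  # probability an elongating P-site stays in frame
    tis_fraction: float = 0.10  # share of non-noise reads initiating at the TIS
    noise: float = 0.02  # share of reads with an off-CDS (UTR) P-site
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.length_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length probabilities sum to {total}, expected 1")
        for length in self.length_probs:
            if length not in self.offsets:
                raise ValueError(f"no true offset defined for length {length}")
            if not 1 <= self.offsets[length] <= length - 1:
                raise ValueError(
                    f"offset {self.offsets[length]} out of range for length {length}"
                )
        if not 1 / 3 <= self.periodicity <= 1:
            raise ValueError("periodicity must lie in [1/3, 1]")
        if not 0 <= self.noise < 1 or not 0 <= self.tis_fraction <= 1:
            raise ValueError("noise and tis_fraction must be probabilities")
        for lo, hi in (self.utr5_range, self.cds_range, self.utr3_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must satisfy 1 <= lo <= hi")
        if self.cds_range[1] < 9:
            raise ValueError("CDS range too short for start + one codon + stop")


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate a transcript annotation table and matching sequences.

    CDS lengths are multiples of 3; every sequence carries ATG at the
    CDS start and TAA at the stop codon. Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    sequences: dict[str, str] = {}
    for i in range(config.n_transcripts):
        tid = f"tx{i + 1:04d}"
        l_utr5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        l_cds = int(rng.integers(config.cds_range[0], config.cds_range[1] + 1))
        l_cds = max(9, l_cds - l_cds % 3)
        l_utr3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        l_tr = l_utr5 + l_cds + l_utr3
        seq = rng.choice(BASES, size=l_tr)
        s, e = l_utr5 + 1, l_utr5 + l_cds
        seq[s - 1 : s + 2] = list("ATG")
        seq[e - 3 : e] = list("TAA")
        rows.append((tid, l_tr, l_utr5, l_cds, l_utr3))
        sequences[tid] = "".join(seq)
    annotation = pd.DataFrame(
        rows, columns=["transcript", "l_tr", "l_utr5", "l_cds", "l_utr3"]
    )
    return annotation, sequences


def simulate_reads(
    annotation: pd.DataFrame,
    config: SimulationConfig,
    n_reads: int = 50_000,
    sample: str = "sim",
) -> pd.DataFrame:
    """Generate footprints with extremities implied by the true offsets.

    Reads whose extremities would fall outside the transcript are
    rejected and redrawn, so the output always holds exactly
    ``n_reads`` rows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    lengths = np.array(sorted(config.length_probs))
    probs = np.array([config.length_probs[L] for L in lengths], dtype=float)
    probs = probs / probs.sum()
    offset_of = np.vectorize(config.offsets.__getitem__)

    l_utr5 = annotation["l_utr5"].to_numpy()
    l_cds = annotation["l_cds"].to_numpy()
    l_tr = annotation["l_tr"].to_numpy()
    tx_names = annotation["transcript"].to_numpy()
    n_tx = len(annotation)

    out_tx = np.empty(n_reads, dtype=object)
    out_end5 = np.zeros(n_reads, dtype=int)
    out_len = np.zeros(n_reads, dtype=int)
    pending = np.arange(n_reads)
    for _ in range(1000):
        if len(pending) == 0:
            break
        m = len(pending)
        tx = rng.integers(0, n_tx, size=m)
        L = rng.choice(lengths, size=m, p=probs)
        s = l_utr5[tx] + 1
        e = l_utr5[tx] + l_cds[tx]

        u = rng.random(m)
        is_noise = u < config.noise
        is_tis = ~is_noise & (rng.random(m) < config.tis_fraction)
        is_elong = ~is_noise & ~is_tis

        psite = np.empty(m, dtype=int)
        psite[is_tis] = s[is_tis]
        # elongating: uniform in-frame codon start, occasionally shifted
        n_codons = l_cds[tx] // 3
        codon_idx = (rng.random(m) * n_codons).astype(int)
        pos = s + 3 * codon_idx
        shift_mask = rng.random(m) > config.periodicity
        pos = pos + shift_mask * rng.integers(1, 3, size=m)
        psite[is_elong] = pos[is_elong]
        # noise: uniform over the two UTRs, weighted by their sizes
        utr_total = l_tr[tx] - l_cds[tx]
        upos = (rng.random(m) * utr_total).astype(int)  # 0-based within UTRs
        noise_pos = np.where(
            upos < l_utr5[tx], upos + 1, upos - l_utr5[tx] + e + 1
        )
        psite[is_noise] = noise_pos[is_noise]

        end5 = psite - offset_of(L)
        end3 = end5 + L - 1
        valid = (end5 >= 1) & (end3 <= l_tr[tx])
        accepted = pending[valid]
        out_tx[accepted] = tx_names[tx[valid]]
        out_end5[accepted] = end5[valid]
        out_len[accepted] = L[valid]
        pending = pending[~valid]
    if len(pending):  # pragma: no cover - pathological configurations only
        raise RuntimeError("read rejection loop failed to converge")

    reads = pd.DataFrame(
        {
            "sample": sample,
            "transcript": out_tx,
            "end5": out_end5,
            "end3": out_end5 + out_len - 1,
            "length": out_len,
        }
    )[READ_COLUMNS]
    return reads.sort_values(["transcript", "end5"], kind="stable").reset_index(
        drop=True
    )


def write_bam(
    reads: pd.DataFrame,
    annotation: pd.DataFrame,
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write simulated reads as a transcriptome-space BAM file.

    Ungapped alignments (CIGAR ``{L}M``) so that parsing them back
    reproduces the read table exactly.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": tx, "LN": int(lt)}
            for tx, lt in zip(annotation["transcript"], annotation["l_tr"])
        ],
    }
    ref_id = {tx: i for i, tx in enumerate(annotation["transcript"])}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, row in enumerate(reads.itertuples(index=False)):
            aln = pysam.AlignedSegment(bam.header)
            aln.query_name = f"read{i + 1}"
            aln.flag = 0
            aln.reference_id = ref_id[row.transcript]
            aln.reference_start = row.end5 - 1
            aln.mapping_quality = 255
            aln.cigartuples = [(0, row.length)]
            if sequences is not None:
                aln.query_sequence = sequences[row.transcript][
                    row.end5 - 1 : row.end3
                ]
            bam.write(aln)


def true_offset_table(config: SimulationConfig) -> pd.DataFrame:
    """The ground-truth per-length offsets as a table (``length, cpo5, cpo3``)."""
    rows = [
        {"length": L, "cpo5": o, "cpo3": L - 1 - o}
        for L, o in sorted(config.offsets.items())
    ]
    return pd.DataFrame(rows)
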