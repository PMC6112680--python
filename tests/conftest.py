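import pandas as pd
import pytest

from psitekit import SimulationConfig, simulate_annotation, simulate_reads


@pytest.fixture()
def toy_annotation() -> pd.DataFrame:
    """Three coding transcripts and one non-coding, hand-checkable geometry."""
    return pd.DataFrame(
        {
            "transcript": ["tx1", "tx2", "tx3", "nc1"],
            "l_tr": [1000, 500, 400, 300],
            "l_utr5": [100, 50, 40, 0],
            "l_cds": [600, 300, 300, 0],
            "l_utr3": [300, 150, 60, 300],
        }
    )


def make_reads(rows):
    """Rows of (transcript, end5, length) -> read table."""
    df = pd.DataFrame(rows, columns=["transcript", "end5", "length"])
    df["end3"] = df["end5"] + df["length"] - 1
    df["sample"] = "s1"
    return df[["sample", "transcript", "end5", "end3", "length"]]


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_transcripts=60, seed=11)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    annotation, sequences = simulate_annotation(sim_config)
    reads = simulate_reads(annotation, sim_config, n_reads=12_000)
    return annotation, sequences, reads
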