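"""Offset-estimation unit and oracle tests.

Brute-force oracles re-implement the window argmax, the weighted mode
and the local-maximum scan by direct enumeration, independent of the
library code paths they check.
"""

from collections import Counter

import numpy as np
import pytest

from psitekit import (
    FIVE_PRIME,
    THREE_PRIME,
    OffsetEstimationError,
    SimulationConfig,
    build_tis_profiles,
    compute_psite_offsets,
    correct_offsets,
    local_maxima,
    optimal_offset,
    simulate_annotation,
    simulate_reads,
    temporary_offsets,
)
from psitekit.offsets import TisProfileSet

from conftest import make_reads


def profiles_from(counts5, counts3, length, flanking=9, n_reads=None):
    ps = TisProfileSet(flanking=flanking)
    ps.counts[(length, FIVE_PRIME)] = Counter(counts5)
    ps.counts[(length, THREE_PRIME)] = Counter(counts3)
    ps.n_tis_reads[length] = n_reads if n_reads is not None else sum(counts5.values())
    return ps


# ---------------------------------------------------------------- profiles

def test_tis_spanning_read_contributes_both_ends(toy_annotation):
    # tx1: s=101. Read 89..116 (L=28) spans the TIS.
    reads = make_reads([("tx1", 89, 28)])
    ps = build_tis_profiles(reads, toy_annotation)
    assert ps.profile(28, FIVE_PRIME)[-12] == 1
    assert ps.profile(28, THREE_PRIME)[15] == 1
    assert ps.n_tis_reads[28] == 1


def test_read_inside_cds_contributes_nothing(toy_annotation):
    reads = make_reads([("tx1", 102, 28), ("tx1", 89, 28)])
    ps = build_tis_profiles(reads, toy_annotation)
    assert ps.n_tis_reads[28] == 1


def test_transcript_without_utr5_excluded(toy_annotation):
    # nc1 is non-coding; also place a spanning read on a transcript with
    # l_utr5 = 0 and check it cannot anchor.
    ann = toy_annotation.copy()
    ann.loc[len(ann)] = ["nout", 400, 0, 300, 100]
    reads = make_reads([("nout", 1, 28)])
    with pytest.raises(OffsetEstimationError):
        build_tis_profiles(reads, ann)


def test_profiles_equal_brute_force_tally(toy_annotation):
    reads = make_reads(
        [
            ("tx1", 89, 28),
            ("tx1", 90, 28),
            ("tx1", 90, 28),
            ("tx2", 40, 30),
            ("tx2", 45, 30),
        ]
    )
    ps = build_tis_profiles(reads, toy_annotation)
    s = {"tx1": 101, "tx2": 51}
    expected5 = Counter()
    expected3 = Counter()
    for row in reads.itertuples():
        if row.end5 <= s[row.transcript] <= row.end3 and row.length == 28:
            expected5[row.end5 - s[row.transcript]] += 1
            expected3[row.end3 - s[row.transcript]] += 1
    assert ps.profile(28, FIVE_PRIME) == expected5
    assert ps.profile(28, THREE_PRIME) == expected3
    total5 = sum(sum(ps.profile(L, FIVE_PRIME).values()) for L in ps.lengths())
    total3 = sum(sum(ps.profile(L, THREE_PRIME).values()) for L in ps.lengths())
    assert total5 == total3 == sum(ps.n_tis_reads.values())


# ------------------------------------------------------- temporary offsets

def test_temporary_offsets_length28_worked_pair():
    """Profiles peaking at x=-11 (5') and x=16 (3') give the pair (11, 16)."""
    ps = profiles_from({-11: 10, -14: 3}, {16: 9, 13: 2}, 28)
    assert temporary_offsets(ps, 28) == (11, 16)


def test_temporary_offsets_single_read():
    ps = profiles_from({-12: 1}, {15: 1}, 28)
    assert temporary_offsets(ps, 28) == (12, 15)


def test_temporary_offsets_tie_toward_smaller_magnitude():
    ps = profiles_from({-11: 5, -13: 5}, {14: 5, 16: 5}, 28)
    assert temporary_offsets(ps, 28) == (11, 14)


def test_temporary_offsets_respect_flanking_windows():
    # Signal only outside the windows: x=-5 is closer than FL=9 to the
    # TIS, x=25 beyond L-FL-1=18 for L=28.
    ps = profiles_from({-5: 10}, {25: 10}, 28)
    assert temporary_offsets(ps, 28) == (None, None)


def brute_force_tpo(profile, window, to_offset):
    best = None
    for x in window:
        if profile.get(x, 0) == 0:
            continue
        cand = (profile[x], to_offset(x))
        if best is None or cand[0] > best[0] or (cand[0] == best[0] and abs(cand[1]) < abs(best[1])):
            best = cand
    return None if best is None else best[1]


def test_temporary_offsets_agree_with_enumeration_on_random_profiles():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        L = int(rng.integers(20, 45))
        fl = 9
        xs5 = rng.integers(-L - 5, 5, size=rng.integers(1, 12))
        xs3 = rng.integers(-5, L + 5, size=rng.integers(1, 12))
        ps = profiles_from(
            Counter({int(x): int(rng.integers(1, 10)) for x in xs5}),
            Counter({int(x): int(rng.integers(1, 10)) for x in xs3}),
            L,
        )
        tpo5, tpo3 = temporary_offsets(ps, L)
        assert tpo5 == brute_force_tpo(
            ps.profile(L, FIVE_PRIME), range(-L + fl, -fl + 1), lambda x: -x
        )
        assert tpo3 == brute_force_tpo(
            ps.profile(L, THREE_PRIME), range(fl - 1, L - fl), lambda x: x
        )


# --------------------------------------------------------- optimal offset

TABLE2 = {
    19: (0.888, 2, 16), 20: (0.986, 4, 15), 21: (1.203, 4, 16),
    22: (1.113, 5, 16), 23: (1.335, 6, 16), 24: (2.191, 7, 16),
    25: (2.494, 8, 16), 26: (3.743, 10, 15), 27: (11.891, 10, 16),
    28: (34.943, 11, 16), 29: (29.125, 12, 16), 30: (7.771, 12, 17),
    31: (1.194, 11, 19), 32: (0.365, 15, 16), 33: (0.235, 16, 16),
    34: (0.164, 17, 16), 35: (0.115, 18, 16), 36: (0.087, 10, 25),
    37: (0.057, 20, 16), 38: (0.034, 21, 16),
}


def test_optimal_offset_published_worked_example():
    """Twenty length bins of a mouse brain dataset select 16 nt, 3' side."""
    tpos = {L: (t5, t3) for L, (_, t5, t3) in TABLE2.items()}
    weights = {L: pct for L, (pct, _, _) in TABLE2.items()}
    assert optimal_offset(tpos, weights) == (16, THREE_PRIME)


def test_optimal_offset_single_bin_prefers_five_prime():
    # One bin: both extremities' modes have equal frequency, 5' wins.
    assert optimal_offset({28: (11, 16)}, {28: 10}) == (11, FIVE_PRIME)


def test_optimal_offset_agrees_with_brute_force_weighted_count():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n_bins = int(rng.integers(1, 8))
        tpos = {}
        weights = {}
        for i, L in enumerate(range(26, 26 + n_bins)):
            tpos[L] = (int(rng.integers(8, 16)), int(rng.integers(13, 20)))
            weights[L] = int(rng.integers(0, 30))
        if not any(w > 0 for w in weights.values()):
            weights[26] = 1
        opo, side = optimal_offset(tpos, weights)
        # enumeration oracle
        freq5, freq3 = Counter(), Counter()
        for L, (t5, t3) in tpos.items():
            freq5[t5] += weights[L]
            freq3[t3] += weights[L]
        freq5 = {k: v for k, v in freq5.items() if v > 0}
        freq3 = {k: v for k, v in freq3.items() if v > 0}
        best5 = min((o for o, w in freq5.items() if w == max(freq5.values())), default=None) if freq5 else None
        best3 = min((o for o, w in freq3.items() if w == max(freq3.values())), default=None) if freq3 else None
        if best5 is not None and (best3 is None or freq5[best5] >= freq3[best3]):
            assert (opo, side) == (best5, FIVE_PRIME)
        else:
            assert (opo, side) == (best3, THREE_PRIME)


def test_optimal_offset_all_zero_weights_fatal():
    with pytest.raises(OffsetEstimationError):
        optimal_offset({28: (11, 16)}, {28: 0})


# ----------------------------------------------------------- local maxima

@pytest.mark.parametrize(
    "values,expected",
    [
        ({0: 1, 1: 3, 2: 1}, [1]),
        ({0: 3, 1: 1, 2: 3}, [0, 2]),          # boundaries count
        ({0: 1, 1: 3, 2: 3, 3: 1}, [1]),       # plateau -> first position
        ({0: 2, 1: 2, 2: 2}, [0]),             # flat positive window
        ({}, []),                               # empty profile
        ({0: 0, 1: 0}, []),                     # zeros are never maxima
    ],
)
def test_local_maxima_cases(values, expected):
    assert local_maxima(Counter(values), range(0, max(values, default=0) + 1)) == expected


def brute_force_local_maxima(profile, window):
    xs = list(window)
    vals = [profile.get(x, 0) for x in xs]
    out = []
    i = 0
    while i < len(xs):
        j = i
        while j + 1 < len(xs) and vals[j + 1] == vals[i]:
            j += 1
        if vals[i] > 0 and (i == 0 or vals[i - 1] < vals[i]) and (
            j == len(xs) - 1 or vals[j + 1] < vals[i]
        ):
            out.append(xs[i])
        i = j + 1
    return out


def test_local_maxima_agree_with_enumeration_on_random_profiles():
    rng = np.random.default_rng(13)
    for _ in range(1000):
        width = int(rng.integers(1, 100))
        lo = int(rng.integers(-50, 10))
        profile = Counter(
            {lo + int(i): int(v) for i, v in enumerate(rng.integers(0, 5, size=width))}
        )
        window = range(lo, lo + width)
        assert local_maxima(profile, window) == brute_force_local_maxima(profile, window)


# -------------------------------------------------------------- correction

def test_correction_published_length31_case():
    """3' profile with maxima at offsets 19 and 17, oPO 16 -> corrected 17.

    Reproduces the published length-31 bin: temporary 11/19 corrected
    to 13/17.
    """
    # 3' profile: global max at x=19, local max at x=17
    counts3 = {19: 10, 18: 2, 17: 6, 16: 1, 12: 3}
    ps = profiles_from({-11: 10}, counts3, 31)
    tpo5, tpo3 = temporary_offsets(ps, 31)
    assert (tpo5, tpo3) == (11, 19)
    corrected = correct_offsets(ps, {31: tpo3}, opo=16, extremity=THREE_PRIME)
    assert corrected[31] == (13, 17)


def test_correction_noop_when_tpo_equals_opo():
    ps = profiles_from({-11: 5}, {16: 5}, 28)
    corrected = correct_offsets(ps, {28: 16}, opo=16, extremity=THREE_PRIME)
    assert corrected[28] == (11, 16)


def test_correction_distance_tie_broken_toward_tpo():
    # candidates {14, 18}, oPO 16, tPO 18 -> 18
    counts3 = {18: 10, 14: 8}
    ps = profiles_from({-9: 10}, counts3, 28)
    corrected = correct_offsets(ps, {28: 18}, opo=16, extremity=THREE_PRIME)
    assert corrected[28] == (9, 18)


def test_correction_fallback_to_opo_for_empty_bins():
    ps = profiles_from({-11: 5}, {16: 5}, 28)
    corrected = correct_offsets(ps, {30: None}, opo=16, extremity=THREE_PRIME)
    assert corrected[30] == (13, 16)


def test_correction_idempotent_when_all_at_opo():
    ps = profiles_from({-11: 5}, {16: 5}, 28)
    first = correct_offsets(ps, {28: 16}, opo=16, extremity=THREE_PRIME)
    again = correct_offsets(ps, {28: first[28][1]}, opo=16, extremity=THREE_PRIME)
    assert first == again


# ------------------------------------------------------------ end-to-end

def test_offset_complementarity_on_pipeline_output(sim_data):
    annotation, _, reads = sim_data
    table = compute_psite_offsets(reads, annotation)
    assert (table["cpo5"] + table["cpo3"] == table["length"] - 1).all()


def test_parameter_recovery_on_simulated_reads(sim_config, sim_data):
    """Exact recovery of the generating offsets for well-covered lengths."""
    annotation, _, reads = sim_data
    table = compute_psite_offsets(reads, annotation)
    recovered = dict(zip(table["length"], table["cpo5"]))
    for length, true_offset in sim_config.offsets.items():
        if table.set_index("length")["n_tis_reads"].get(length, 0) >= 50:
            assert recovered[length] == true_offset


def test_per_sample_estimation_independent(sim_data):
    annotation, _, reads = sim_data
    half = len(reads) // 2
    two = reads.copy()
    two.loc[two.index[half:], "sample"] = "s2"
    table = compute_psite_offsets(two, annotation)
    assert set(table["sample"]) == {"sim", "s2"}
    for _, grp in table.groupby("sample"):
        assert (grp["cpo5"] + grp["cpo3"] == grp["length"] - 1).all()
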