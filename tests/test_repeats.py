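"""SSR scanning against a brute-force oracle, tandem and pair repeats."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plastokit as pk
from plastokit._seq import random_seq, revcomp
from plastokit.repeats import DEFAULT_SSR_THRESHOLDS, is_primitive


# --- independent oracle -----------------------------------------------------

def brute_force_ssrs(seq, thresholds=DEFAULT_SSR_THRESHOLDS):
    """All maximal primitive runs meeting the thresholds, by direct check of
    every (start, unit-length) pair."""
    n = len(seq)
    found = set()
    for u, thr in thresholds.items():
        for i in range(n - u * thr + 1):
            unit = seq[i:i + u]
            if "N" in unit or not is_primitive(unit):
                continue
            # maximal: not extendable leftward by one base
            if i > 0 and seq[i - 1] != "N" and seq[i - 1] == seq[i + u - 1]:
                continue
            copies = 1
            while seq[i + copies * u:i + (copies + 1) * u] == unit:
                copies += 1
            if copies >= thr:
                found.add((i, i + copies * u, pk.canonical_motif(unit)))
    return found


@pytest.mark.parametrize("seed", range(30))
def test_find_ssrs_equals_brute_force_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    # low-entropy alphabet mix so runs actually occur
    seq = "".join(rng.choice(list("AACGTT"), size=2000))
    got = {(s.start, s.end, s.motif) for s in pk.find_ssrs(seq)}
    assert got == brute_force_ssrs(seq)


@pytest.mark.parametrize("seq,expect", [
    ("A" * 10, [(0, 10, "A", 10)]),            # at threshold
    ("A" * 9, []),                              # below threshold
    ("C" + "AT" * 5 + "G", [(1, 11, "AT", 5)]),
    ("AT" * 4, []),                             # 4 < 5 copies for di
    ("ACG" * 4, [(0, 12, "ACG", 4)]),
    ("N" * 4 + "A" * 10, [(4, 14, "A", 10)]),   # N breaks and restarts runs
])
def test_find_ssrs_examples(seq, expect):
    got = [(s.start, s.end, s.motif, s.copies) for s in pk.find_ssrs(seq)]
    assert got == expect


def test_ssr_runs_are_maximal_and_phase_collapsed(small_family):
    anc, _, _ = small_family
    ssrs = pk.find_ssrs(anc.seq)
    seen = set()
    for s in ssrs:
        u = len(s.motif)
        assert (s.end - s.start) == u * s.copies
        # maximal: one more unit fails on either side
        assert anc.seq[s.start - u:s.start] != anc.seq[s.start:s.start + u]
        assert anc.seq[s.end:s.end + u] != anc.seq[s.end - u:s.end]
        key = (s.start, s.end)
        assert key not in seen  # a run is reported exactly once
        seen.add(key)


@given(st.text(alphabet="ACGT", min_size=1, max_size=6))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_canonical_motif_is_rotation_invariant(unit):
    canon = pk.canonical_motif(unit)
    for i in range(len(unit)):
        assert pk.canonical_motif(unit[i:] + unit[:i]) == canon
    assert is_primitive(canon)
    if is_primitive(unit):
        assert len(canon) == len(unit)
        assert canon == min(unit[i:] + unit[:i] for i in range(len(unit)))


@pytest.mark.parametrize("unit,expect", [
    ("TA", "AT"), ("GAA", "AAG"), ("ATAT", "AT"), ("CCC", "C"),
])
def test_canonical_motif_examples(unit, expect):
    assert pk.canonical_motif(unit) == expect


# --- tandem -----------------------------------------------------------------

def test_tandem_perfect_array_hand_scored():
    # the bare array: 35 aligned positions x +2 = 70, no mismatches
    hits = pk.find_tandem_repeats("ACGTGCA" * 5)
    assert len(hits) == 1
    assert (hits[0].score, hits[0].identity, hits[0].unit_len) == (70, 1.0, 7)
    # embedded in random context it is still found, full length
    rng = np.random.default_rng(1)
    seq = random_seq(rng, 400, 0.4) + "ACGTGCA" * 5 + random_seq(rng, 400, 0.4)
    hits = [h for h in pk.find_tandem_repeats(seq) if h.unit_len == 7]
    assert len(hits) == 1
    a, b = hits[0].intervals[0]
    assert a <= 400 and b >= 435 and hits[0].score >= 70


def test_tandem_unit_below_minimum_not_reported():
    rng = np.random.default_rng(2)
    seq = random_seq(rng, 300, 0.4) + "ACGTGC" * 10 + random_seq(rng, 300, 0.4)
    for h in pk.find_tandem_repeats(seq, min_unit=7):
        a, b = h.intervals[0]
        assert not (a < 360 and b > 300)  # the unit-6 array is not called


def test_tandem_with_mismatch_detected_below_full_identity():
    cfg = pk.SynthConfig.small(seed=3, repeat_plan=[
        pk.PlannedRepeat("tandem", 9, 0.96, "SSC", 3280, copies=8)])
    anc, truth = pk.build_ancestor(cfg)
    t = truth.repeats[0]
    (a, b), = t["intervals"]
    hits = [h for h in pk.find_tandem_repeats(anc.seq)
            if h.intervals[0][0] < b and h.intervals[0][1] > a]
    assert hits and hits[0].identity < 1.0
    assert hits[0].unit_len == 9


# --- pair repeats -----------------------------------------------------------

def test_planted_pair_repeats_found(small_family):
    anc, _, truth = small_family
    disp = pk.find_pair_repeats(anc.seq, "dispersed")
    pal = pk.find_pair_repeats(anc.seq, "palindromic")
    for t in truth.repeats:
        if t["kind"] == "tandem":
            continue
        hits = disp if t["kind"] == "dispersed" else pal
        (a1, b1), (a2, b2) = t["intervals"]
        match = [h for h in hits
                 if h.intervals[0][0] <= a1 and h.intervals[0][1] >= b1
                 and h.intervals[1][0] <= a2 and h.intervals[1][1] >= b2]
        assert match, f"planted {t['kind']} repeat missed"
        assert match[0].length >= t["length"]


def test_pair_identity_threshold():
    """0.92-identity pairs pass the 0.90 screen; 0.88 pairs do not."""
    rng = np.random.default_rng(7)
    core = random_seq(rng, 50, 0.5)

    def plant(positions):
        copy = list(core)
        for p in positions:
            copy[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[p]]
        return (random_seq(rng, 2000, 0.4) + core +
                random_seq(rng, 1000, 0.4) + "".join(copy) +
                random_seq(rng, 2000, 0.4))

    # 4 mismatches clustered at the start: the pair is 92 % identical and a
    # clean seed exists downstream -> detected
    hits_92 = pk.find_pair_repeats(plant([0, 2, 4, 6]), "dispersed", min_len=30)
    assert any(h.length >= 30 and h.identity >= 0.9 for h in hits_92)
    # 6 mismatches spread every 8 bp: no >=45 bp window reaches 90 % identity
    # (a brute-force all-pairs scan would find nothing either) -> absent
    hits_88 = pk.find_pair_repeats(plant([4, 12, 20, 28, 36, 44]),
                                   "dispersed", min_len=45)
    assert not [h for h in hits_88 if h.length >= 45]


def test_exact_pair_modes():
    rng = np.random.default_rng(9)
    x = random_seq(rng, 40, 0.5)
    seq = (random_seq(rng, 3000, 0.4) + x + random_seq(rng, 5000, 0.4) +
           x + random_seq(rng, 1000, 0.4) + revcomp(x) +
           random_seq(rng, 2000, 0.4))
    disp = pk.find_pair_repeats(seq, "dispersed")
    assert any(h.identity >= 0.95 and h.length >= 40 for h in disp)
    pal = pk.find_pair_repeats(seq, "palindromic")
    assert len(pal) >= 2  # x pairs with revcomp(x) at two loci


def test_revcomp_maps_hit_sets_bijectively(small_family):
    anc, _, _ = small_family
    n = len(anc)
    rc = revcomp(anc.seq)

    def key(hits):
        return sorted(tuple(sorted((b - a, d - c) for (a, b), (c, d)
                                   in [h.intervals])) for h in hits)

    for kind in ("dispersed", "palindromic"):
        fwd = pk.find_pair_repeats(anc.seq, kind)
        bwd = pk.find_pair_repeats(rc, kind)
        # same number of hits with the same length spectrum
        assert sorted(h.length for h in fwd) == sorted(h.length for h in bwd)


# --- summary ----------------------------------------------------------------

def test_region_summary_counts_and_flags(small_family):
    anc, _, truth = small_family
    ssrs = pk.find_ssrs(anc.seq)
    summ = pk.ssr_region_summary(ssrs, truth.partition, anc.genes)
    assert int(summ.region_counts.get("LSC", 0)) >= 10
    assert abs(summ.class_percent.sum() - 100) < 1e-9
    for hs in truth.hotspot_spacers:
        assert hs in summ.flagged  # three SSRs planted in each hotspot
    assert summ.context_counts.get("intergenic", 0) >= summ.context_counts.get("genic", 0)


def test_summary_flag_threshold_boundary(small_family):
    anc, _, truth = small_family
    ssrs = [s for s in pk.find_ssrs(anc.seq)]
    summ3 = pk.ssr_region_summary(ssrs, truth.partition, anc.genes, flag_min=3)
    summ4 = pk.ssr_region_summary(ssrs, truth.partition, anc.genes, flag_min=4)
    assert set(summ4.flagged) <= set(summ3.flagged)
    only3 = set(summ3.flagged) - set(summ4.flagged)
    for name in only3:
        assert summ3.locus_counts.loc[name, "n_ssrs"] == 3
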