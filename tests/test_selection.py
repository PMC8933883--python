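"""NG86 Ka/Ks against an exhaustive pathway-enumeration oracle."""
import itertools
import math

import numpy as np
import pytest

import plastokit as pk
from plastokit.errors import SaturationError
from plastokit.selection import FrameError

BASES = "ACGT"

# --- independent oracle: explicit recursion over substitution pathways ------

_CODE11 = None


def _code11():
    global _CODE11
    if _CODE11 is None:
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        t = unambiguous_dna_by_id[11]
        _CODE11 = (dict(t.forward_table), set(t.stop_codons))
    return _CODE11


def oracle_sites(codon):
    """Synonymous site count of one codon (stop-creating changes count as
    nonsynonymous)."""
    fwd, stops = _code11()
    syn = 0.0
    for p, b in itertools.product(range(3), BASES):
        if b == codon[p]:
            continue
        alt = codon[:p] + b + codon[p + 1:]
        if alt not in stops and fwd[alt] == fwd[codon]:
            syn += 1 / 3
    return syn


def oracle_diffs(c1, c2):
    fwd, stops = _code11()

    def walk(cur, remaining):
        """Yield (syn, nonsyn, hit_stop) over all substitution orders."""
        if not remaining:
            yield 0.0, 0.0, False
            return
        for idx, p in enumerate(remaining):
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            step_stop = nxt in stops
            step_syn = (not step_stop and cur not in stops
                        and fwd[cur] == fwd[nxt])
            for s, n, hs in walk(nxt, remaining[:idx] + remaining[idx + 1:]):
                yield (s + (1 if step_syn else 0),
                       n + (0 if step_syn else 1),
                       hs or step_stop)

    diff_pos = tuple(p for p in range(3) if c1[p] != c2[p])
    paths = list(walk(c1, diff_pos))
    clean = [p for p in paths if not p[2]] or paths
    s = sum(p[0] for p in clean) / len(clean)
    n = sum(p[1] for p in clean) / len(clean)
    return s, n


def oracle_kaks(a, b):
    fwd, stops = _code11()
    S = N = Sd = Nd = 0.0
    for c in range(len(a) // 3):
        c1, c2 = a[3 * c:3 * c + 3], b[3 * c:3 * c + 3]
        if c1 in stops or c2 in stops:
            continue
        s = 0.5 * (oracle_sites(c1) + oracle_sites(c2))
        S += s
        N += 3 - s
        sd, nd = oracle_diffs(c1, c2)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return (jc(pn) if pn else 0.0), (jc(ps) if ps else 0.0)


def random_cds(rng, n_codons):
    fwd, stops = _code11()
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def mutate_cds(rng, cds, n_mut):
    fwd, stops = _code11()
    out = list(cds)
    done = 0
    while done < n_mut:
        p = int(rng.integers(len(out)))
        old = out[p]
        new = BASES[(BASES.index(old) + 1 + int(rng.integers(3))) % 4]
        out[p] = new
        c0 = 3 * (p // 3)
        if "".join(out[c0:c0 + 3]) in stops:
            out[p] = old
            continue
        done += 1
    return "".join(out)


@pytest.mark.parametrize("seed", range(50))
def test_ng86_matches_pathway_oracle(seed):
    rng = np.random.default_rng(seed)
    a = random_cds(rng, 30)
    b = mutate_cds(rng, a, int(rng.integers(1, 15)))
    rec = pk.ng86_kaks(a, b)
    ka_o, ks_o = oracle_kaks(a, b)
    assert rec.ka == pytest.approx(ka_o, abs=1e-9)
    assert rec.ks == pytest.approx(ks_o, abs=1e-9)


def test_identical_pair_zero():
    rng = np.random.default_rng(1)
    a = random_cds(rng, 40)
    rec = pk.ng86_kaks(a, a)
    assert rec.ka == 0.0 and rec.ks == 0.0
    assert rec.omega is None  # undefined iff ks == 0
    assert rec.n_sites + rec.s_sites == pytest.approx(rec.n_codons * 3)


def test_two_step_codon_equals_pathway_average():
    """TTT->GGT differs at two positions; both pathway orders are averaged."""
    a = "ATGTTTAAA"
    b = "ATGGGTAAA"
    rec = pk.ng86_kaks(a, b)
    sd, nd = oracle_diffs("TTT", "GGT")
    assert rec.sd == pytest.approx(sd, abs=1e-12)
    assert rec.nd == pytest.approx(nd, abs=1e-12)
    assert rec.sd + rec.nd == pytest.approx(2.0)


def test_synonymous_third_position_change():
    a = "GGA" * 100
    b = "GGG" + "GGA" * 99
    rec = pk.ng86_kaks(a, b)
    assert rec.ka == 0.0 and rec.ks > 0


def test_jc_correction_reduces_to_p_at_small_p():
    from plastokit._seq import jc69_distance
    p = 1e-4
    # d = p + (2/3)p^2 + O(p^3): agreement to 1e-6 absolute at p = 1e-4
    assert jc69_distance(p) == pytest.approx(p, abs=1e-6)
    assert jc69_distance(p) > p


def test_symmetry():
    rng = np.random.default_rng(3)
    a = random_cds(rng, 25)
    b = mutate_cds(rng, a, 8)
    r1, r2 = pk.ng86_kaks(a, b), pk.ng86_kaks(b, a)
    assert (r1.ka, r1.ks) == (r2.ka, r2.ks)


def test_internal_stop_and_frame_errors():
    with pytest.raises(FrameError, match="codon 2"):
        pk.ng86_kaks("ATGTAACCC", "ATGAAACCC")
    with pytest.raises(FrameError):
        pk.ng86_kaks("ATGA", "ATGA")


def test_gap_and_n_codons_masked():
    a = "ATGNNNAAATTT"
    b = "ATGCCCAAATTT"
    rec = pk.ng86_kaks(a, b)
    assert rec.n_codons == 3  # the N codon is excluded pairwise


def test_screen_flags_nonsynonymous_only_gene(toy_alignment):
    rng = np.random.default_rng(4)
    base = random_cds(rng, 60)
    fwd, stops = _code11()

    def nonsyn_variant(seed):
        # many nonsynonymous changes plus a single synonymous one so ks > 0
        # and omega is defined (and far above 1)
        r = np.random.default_rng(seed)
        out = list(base)
        done = -1
        while done < 0:
            c = int(r.integers(60))
            codon = base[3 * c:3 * c + 3]
            new = BASES[int(r.integers(4))]
            cand = codon[:2] + new
            if cand not in stops and fwd[cand] == fwd[codon] and cand != codon:
                out[3 * c + 2] = new
                done = 0
        while done < 10:
            c = int(r.integers(60))
            codon = base[3 * c:3 * c + 3]
            p = int(r.integers(2))  # 1st/2nd positions: mostly nonsynonymous
            new = BASES[(BASES.index(codon[p]) + 1 + int(r.integers(3))) % 4]
            cand = codon[:p] + new + codon[p + 1:]
            if cand in stops or fwd[cand] == fwd[codon]:
                continue
            out[3 * c + p] = new
            done += 1
        return "".join(out)

    def syn_variant(seed):
        r = np.random.default_rng(seed)
        out = list(base)
        done = 0
        while done < 10:
            c = int(r.integers(60))
            codon = "".join(out[3 * c:3 * c + 3])
            new = BASES[int(r.integers(4))]
            cand = codon[:2] + new
            if cand in stops or fwd[cand] != fwd[codon]:
                continue
            out[3 * c + 2] = new
            done += 1
        return "".join(out)

    alns = {
        "under_selection": toy_alignment(
            [base, nonsyn_variant(1), nonsyn_variant(2)], name="g1", cls="coding"),
        "constrained": toy_alignment(
            [base, syn_variant(3), syn_variant(4)], name="g2", cls="coding"),
        "constant": toy_alignment([base, base, base], name="g3", cls="coding"),
    }
    table = pk.gene_selection_screen(alns).set_index("gene")
    assert bool(table.loc["under_selection", "positive_selection"])
    assert not bool(table.loc["constrained", "positive_selection"])
    assert table.loc["constrained", "mean_omega"] == pytest.approx(0.0)
    assert math.isnan(table.loc["constant", "mean_omega"])
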