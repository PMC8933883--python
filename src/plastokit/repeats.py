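"""Repeat scanning: microsatellites (SSRs), tandem arrays and
dispersed/palindromic repeat pairs.

SSRs are maximal perfect tandem runs of primitive 1-6 bp units meeting the
MISA-style class thresholds (mono 10, di 5, tri 4, tetra/penta/hexa 3 by
default). Compound (interrupted) SSRs are not merged; each simple run counts
once. Pair repeats follow the classic 30 bp / 90 % identity screen, with
ungapped extension from exact seeds. The tandem detector is a simplified
Tandem Repeats Finder: exact-seed period proposal, consensus scoring with
+match/-mismatch weights, no probabilistic model.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._seq import revcomp
from .errors import ConsistencyError
from .io import GeneFeature
from .quadripartite import QuadripartitePartition, _extend_xdrop

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

MOTIF_CLASS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRLocus:
    start: int
    end: int
    motif: str      # canonical (lexicographically smallest rotation)
    unit: str       # the unit as it occurs at ``start``
    copies: int
    region: Optional[str] = None
    context: Optional[str] = None   # genic / intergenic
    locus: Optional[str] = None     # gene or spacer name

    def __len__(self):
        return self.end - self.start


@dataclass(frozen=True)
class RepeatHit:
    kind: str                        # dispersed / palindromic / tandem
    intervals: Tuple[Tuple[int, int], ...]
    length: int
    identity: float
    unit_len: Optional[int] = None   # tandem only
    copies: Optional[float] = None
    score: Optional[int] = None


def is_primitive(unit: str) -> bool:
    """True if the unit is not an integer repetition of a shorter unit."""
    return unit not in (unit + unit)[1:-1]


def canonical_motif(unit: str) -> str:
    """Lexicographically smallest rotation of a primitive unit; units that are
    repetitions of a shorter unit are first reduced to that unit."""
    if not 1 <= len(unit) <= 6:
        raise ValueError("unit length must be 1-6")
    for u in range(1, len(unit)):
        if len(unit) % u == 0 and unit == unit[:u] * (len(unit) // u):
            unit = unit[:u]
            break
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def find_ssrs(seq: str, thresholds: Dict[int, int] = None) -> List[SSRLocus]:
    """All maximal perfect SSR runs meeting the class thresholds.

    Each run is reported once, at its leftmost phase, under its shortest
    primitive unit. N breaks runs.
    """
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    n = len(seq)
    out = []
    for u, thr in sorted(thresholds.items()):
        i = 0
        while i + u * thr <= n:
            unit = seq[i:i + u]
            if "N" in unit:
                i += 1
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            copies = (j - i) // u
            if copies >= thr and is_primitive(unit) and \
                    (i == 0 or seq[i - 1] != seq[i + u - 1] or seq[i - 1] == "N"):
                out.append(SSRLocus(start=i, end=i + copies * u,
                                    motif=canonical_motif(unit), unit=unit,
                                    copies=copies))
            i = max(i + 1, j - u + 1)
    out.sort(key=lambda s: (s.start, s.end))
    return out


# ---------------------------------------------------------------------------
# Tandem repeats (simplified TRF)
# ---------------------------------------------------------------------------

def find_tandem_repeats(seq: str, min_unit: int = 7, match: int = 2,
                        mismatch: int = 7, indel: int = 7, min_score: int = 50,
                        max_unit: int = 500) -> List[RepeatHit]:
    """Tandem arrays with unit length >= min_unit scored +match/-mismatch
    against the array consensus; arrays scoring >= min_score are reported and
    overlapping arrays are reduced to the highest-scoring representative."""
    n = len(seq)
    if n < 2 * min_unit:
        return []
    k = min_unit
    occ: Dict[str, int] = {}
    cands = set()
    for i in range(0, n - k + 1):
        km = seq[i:i + k]
        if "N" in km:
            continue
        if km in occ:
            d = i - occ[km]
            if min_unit <= d <= max_unit:
                cands.add((occ[km], d))
        occ[km] = i

    hits = []
    done = set()
    xdrop = 3 * mismatch
    for p, d in sorted(cands):
        # ungapped extension of the lag-d self-alignment, tolerating isolated
        # mismatches (score +match/-mismatch, X-drop stop, trim at the best)
        score, best = 0, 0
        a = best_a = p
        while a > 0:
            a -= 1
            score += match if seq[a] == seq[a + d] else -mismatch
            if score > best:
                best, best_a = score, a
            elif score < best - xdrop:
                break
        a = best_a
        score, best = 0, 0
        b = best_b = p + d + k
        while b < n:
            score += match if seq[b] == seq[b - d] else -mismatch
            b += 1
            if score > best:
                best, best_b = score, b
            elif score < best - xdrop:
                break
        b = best_b
        if (a, b, d) in done:
            continue
        done.add((a, b, d))
        if b - a < 2 * d:
            continue
        # consensus per phase, majority vote
        cons = []
        for ph in range(d):
            counts: Dict[str, int] = {}
            for pos in range(a + ph, b, d):
                counts[seq[pos]] = counts.get(seq[pos], 0) + 1
            cons.append(max(sorted(counts), key=counts.get))
        matches = sum(1 for pos in range(a, b) if seq[pos] == cons[(pos - a) % d])
        score = match * matches - mismatch * (b - a - matches)
        if score >= min_score:
            hits.append(RepeatHit(kind="tandem", intervals=((a, b),),
                                  length=b - a, identity=matches / (b - a),
                                  unit_len=d, copies=round((b - a) / d, 1),
                                  score=score))
    # reduce overlapping arrays to the best-scoring representative
    hits.sort(key=lambda h: (-h.score, h.intervals[0][0]))
    kept: List[RepeatHit] = []
    for h in hits:
        a, b = h.intervals[0]
        if all(b <= x or a >= y for kh in kept for x, y in kh.intervals):
            kept.append(h)
    kept.sort(key=lambda h: h.intervals[0][0])
    return kept


# ---------------------------------------------------------------------------
# Dispersed / palindromic pair repeats
# ---------------------------------------------------------------------------

def find_pair_repeats(seq: str, kind: str, min_len: int = 30,
                      min_identity: float = 0.90, seed_k: int = 20,
                      max_occ: int = 60) -> List[RepeatHit]:
    """Repeat pairs >= min_len at identity >= min_identity: copies on the same
    strand (dispersed) or one copy reverse-complemented (palindromic).

    Exact seed_k-mer matches are extended ungapped; the trivial self-diagonal
    is excluded; symmetric duplicates are collapsed and overlapping hits are
    merged.
    """
    if kind not in ("dispersed", "palindromic"):
        raise ValueError(f"kind must be dispersed or palindromic, not {kind!r}")
    n = len(seq)
    target = seq if kind == "dispersed" else revcomp(seq)
    index: Dict[str, list] = {}
    for j in range(0, n - seed_k + 1):
        km = target[j:j + seed_k]
        if "N" not in km:
            index.setdefault(km, []).append(j)

    diag: Dict[int, list] = {}
    for i in range(0, n - seed_k + 1):
        km = seq[i:i + seed_k]
        if "N" in km:
            continue
        hits = index.get(km, [])
        if len(hits) > max_occ:
            continue
        for j in hits:
            if kind == "dispersed" and j <= i:
                continue
            diag.setdefault(j - i, []).append(i)

    raw = []
    for d, ilist in diag.items():
        ilist.sort()
        clusters = [[ilist[0], ilist[0]]]
        for i in ilist[1:]:
            if i - clusters[-1][1] <= 2 * seed_k:
                clusters[-1][1] = i
            else:
                clusters.append([i, i])
        for lo, hi in clusters:
            a1, a2, j1, j2, ident = _extend_xdrop(
                seq, target, lo, lo + seed_k, lo + d, lo + d + seed_k,
                min_identity)
            if ident < min_identity:
                continue
            if a2 - a1 < min_len:
                continue
            if kind == "dispersed":
                c1, c2 = (a1, a2), (j1, j2)
            else:
                c1, c2 = (a1, a2), (n - j2, n - j1)
            if c1 == c2:
                continue
            c1, c2 = sorted([c1, c2])
            if c1[1] > c2[0]:
                continue  # overlapping copies (e.g. hairpin centre)
            raw.append(RepeatHit(kind=kind, intervals=(c1, c2),
                                 length=a2 - a1, identity=ident))

    # collapse duplicates / merge overlapping hits into one motif
    raw.sort(key=lambda h: h.intervals)
    merged: List[RepeatHit] = []
    for h in raw:
        if merged and _pair_overlaps(merged[-1], h):
            m = merged[-1]
            ivs = tuple((min(x[0], y[0]), max(x[1], y[1]))
                        for x, y in zip(m.intervals, h.intervals))
            merged[-1] = RepeatHit(kind=kind, intervals=ivs,
                                   length=ivs[0][1] - ivs[0][0],
                                   identity=min(m.identity, h.identity))
        else:
            merged.append(h)
    return merged


def _pair_overlaps(a: RepeatHit, b: RepeatHit) -> bool:
    return all(x[0] < y[1] and y[0] < x[1]
               for x, y in zip(a.intervals, b.intervals))


# ---------------------------------------------------------------------------
# Region / context summary
# ---------------------------------------------------------------------------

@dataclass
class SSRSummary:
    table: pd.DataFrame           # one row per SSR with region/context/locus
    class_percent: pd.Series      # mono..hexa percentages
    region_counts: pd.Series      # LSC/IRb/SSC/IRa counts
    context_counts: pd.Series     # genic/intergenic counts
    locus_counts: pd.DataFrame    # per gene/spacer SSR counts with >=k flag
    flagged: List[str] = field(default_factory=list)


def ssr_region_summary(ssrs: Sequence[SSRLocus],
                       partition: QuadripartitePartition,
                       genes: Sequence[GeneFeature],
                       flag_min: int = 3) -> SSRSummary:
    """Summarise SSRs by motif class, genomic region and genic/intergenic
    context, and flag loci (genes or spacers) carrying >= flag_min SSRs."""
    genes = sorted([g for g in genes if g.kind != "intergenic"],
                   key=lambda g: g.start)
    starts = [g.start for g in genes]
    rows = []
    for s in ssrs:
        if s.end > partition.n:
            raise ConsistencyError("SSR outside genome: partition mismatch")
        region = partition.region_of(s.start)
        context, locus = "intergenic", "?"
        idx = bisect.bisect_right(starts, s.start) - 1
        if idx >= 0 and genes[idx].end > s.start:
            context, locus = "genic", genes[idx].name
        else:
            left = genes[idx].name if idx >= 0 else genes[-1].name
            right = genes[idx + 1].name if idx + 1 < len(genes) else genes[0].name
            locus = f"{left}-{right}"
        rows.append({"start": s.start, "end": s.end, "motif": s.motif,
                     "unit_len": len(s.motif),
                     "motif_class": MOTIF_CLASS[len(s.motif)],
                     "copies": s.copies, "region": region,
                     "context": context, "locus": locus})
    table = pd.DataFrame(rows, columns=["start", "end", "motif", "unit_len",
                                        "motif_class", "copies", "region",
                                        "context", "locus"])
    classes = pd.Series(0.0, index=[MOTIF_CLASS[u] for u in range(1, 7)])
    if len(table):
        pct = table["motif_class"].value_counts(normalize=True) * 100
        classes.update(pct)
    region_counts = table["region"].value_counts() if len(table) else pd.Series(dtype=int)
    context_counts = table["context"].value_counts() if len(table) else pd.Series(dtype=int)
    if len(table):
        locus_counts = (table.groupby("locus").size().rename("n_ssrs")
                        .sort_values(ascending=False).to_frame())
        locus_counts["flagged"] = locus_counts["n_ssrs"] >= flag_min
        flagged = list(locus_counts.index[locus_counts["flagged"]])
    else:
        locus_counts = pd.DataFrame(columns=["n_ssrs", "flagged"])
        flagged = []
    return SSRSummary(table=table, class_percent=classes,
                      region_counts=region_counts,
                      context_counts=context_counts,
                      locus_counts=locus_counts, flagged=flagged)
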