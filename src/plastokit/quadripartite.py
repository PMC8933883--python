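"""Quadripartite structure: inverted-repeat detection, LSC/IRb/SSC/IRa
partitioning, junction profiling, boundary typing, and region-size
correlations.

The IR is defined as the maximal-length pair of non-overlapping arcs of the
circle such that one arc matches the reverse complement of the other, ungapped,
at identity >= ``min_identity``. IRb is, by convention, the IR copy whose
clockwise (downstream) neighbour is the SSC, so the clockwise region order is
always LSC-IRb-SSC-IRa.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._seq import revcomp
from .errors import (
    AmbiguousStructureError,
    ConsistencyError,
    StructureNotFoundError,
)
from .io import GeneFeature, Plastome

JUNCTIONS = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")


@dataclass(frozen=True)
class Arc:
    """A directed arc on a circle of size n, 0-based, possibly wrapping."""

    start: int
    length: int
    n: int

    @property
    def end(self) -> int:
        """Exclusive end position, modulo n."""
        return (self.start + self.length) % self.n

    def __len__(self):
        return self.length

    def intervals(self) -> List[Tuple[int, int]]:
        """Linear [start, end) intervals covering the arc."""
        if self.start + self.length <= self.n:
            return [(self.start, self.start + self.length)]
        return [(self.start, self.n), (0, (self.start + self.length) % self.n)]

    def overlaps(self, other: "Arc") -> bool:
        for a, b in self.intervals():
            for c, d in other.intervals():
                if a < d and c < b:
                    return True
        return False


@dataclass(frozen=True)
class IRPair:
    """Two arcs; ``copy2`` matches revcomp(``copy1``) at ``identity``."""

    copy1: Arc
    copy2: Arc
    identity: float

    @property
    def length(self) -> int:
        return self.copy1.length


@dataclass(frozen=True)
class QuadripartitePartition:
    lsc: Arc
    irb: Arc
    ssc: Arc
    ira: Arc
    n: int
    identity: float = 1.0

    def __post_init__(self):
        total = self.lsc.length + self.irb.length + self.ssc.length + self.ira.length
        if total != self.n:
            raise ConsistencyError(f"regions sum to {total}, genome is {self.n}")
        if self.irb.length != self.ira.length:
            raise ConsistencyError("IR copies differ in length")

    @property
    def region_lengths(self) -> Dict[str, int]:
        return {
            "LSC": self.lsc.length,
            "IRb": self.irb.length,
            "SSC": self.ssc.length,
            "IRa": self.ira.length,
        }

    def junction_positions(self) -> Dict[str, int]:
        return {
            "LSC/IRb": self.irb.start,
            "IRb/SSC": self.ssc.start,
            "SSC/IRa": self.ira.start,
            "IRa/LSC": self.lsc.start,
        }

    def region_of(self, pos: int) -> str:
        for name, arc in (("LSC", self.lsc), ("IRb", self.irb), ("SSC", self.ssc), ("IRa", self.ira)):
            for a, b in arc.intervals():
                if a <= pos < b:
                    return name
        raise ValueError(f"position {pos} outside genome")


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _extend_xdrop(s: str, r: str, a1: int, a2: int, j1: int, j2: int,
                  min_identity: float):
    """Extend an exact match with +1/-penalty scoring and an X-drop stop,
    trimming each end at its score maximum. The mismatch penalty is chosen so
    sustained extension requires local identity >= min_identity, which pins
    boundaries of (near-)exact repeats to the base."""
    if min_identity >= 1.0:
        penalty = None
    else:
        penalty = max(1, int(round(min_identity / (1.0 - min_identity))))
    xdrop = 2 * (penalty or 1) + 2
    mm = 0

    def run(i, j, step):
        nonlocal mm
        score, best_score, best, best_mm, cur_mm = 0, 0, (i, j), 0, 0
        while 0 <= i + step < len(s) and 0 <= j + step < len(r):
            i += step
            j += step
            if s[i] == r[j] and s[i] != "N":
                score += 1
                if score > best_score:
                    best_score, best, best_mm = score, (i, j), cur_mm
            else:
                if penalty is None:
                    break
                score -= penalty
                cur_mm += 1
                if score < best_score - xdrop:
                    break
        mm += best_mm
        return best

    i, j = run(a2 - 1, j2 - 1, +1)
    a2, j2 = i + 1, j + 1
    i, j = run(a1, j1, -1)
    a1, j1 = i, j
    identity = 1.0 - mm / (a2 - a1)
    return a1, a2, j1, j2, identity


def detect_inverted_repeats(seq: str, min_len: int = 1000,
                            min_identity: float = 0.99, k: int = 31,
                            circular: bool = True) -> IRPair:
    """Find the maximal inverted-repeat pair of a (circular) genome.

    k-mer seeds of the sequence against its reverse complement are merged
    along anti-diagonals and extended ungapped; ties are broken by (longer,
    then smaller start coordinate). Circularity is handled by logically
    doubling the sequence.
    """
    n = len(seq)
    if n < 4 * min_len:
        raise StructureNotFoundError(
            f"genome ({n} bp) shorter than 4 x min_len ({min_len} bp)")
    s2 = seq + seq if circular else seq
    r2 = revcomp(s2)
    n2 = len(s2)

    # index reverse-complement k-mers
    index: Dict[str, list] = {}
    for j in range(0, n2 - k + 1):
        km = r2[j:j + k]
        index.setdefault(km, []).append(j)

    # seed with strided query k-mers, cluster per diagonal
    stride = max(1, k // 4)
    max_occ = 100  # skip hyper-repetitive (low-complexity) seeds
    diag_seeds: Dict[int, list] = {}
    for i in range(0, n2 - k + 1, stride):
        km = s2[i:i + k]
        if "N" in km:
            continue
        hits = index.get(km)
        if not hits or len(hits) > max_occ:
            continue
        for j in hits:
            diag_seeds.setdefault(j - i, []).append(i)

    candidates = []
    seen = set()
    for d, ilist in diag_seeds.items():
        ilist.sort()
        # merge seeds separated by < 4k on the same diagonal into clusters
        clusters = [[ilist[0], ilist[0]]]
        for i in ilist[1:]:
            if i - clusters[-1][1] <= 4 * k:
                clusters[-1][1] = i
            else:
                clusters.append([i, i])
        for lo, hi in clusters:
            a1, a2, j1, j2, ident = _extend_xdrop(
                s2, r2, lo, lo + k, lo + d, lo + d + k, min_identity)
            length = a2 - a1
            if length < min_len or length * 2 >= n:
                continue
            # map second copy from revcomp coordinates back to the forward strand
            b1, b2 = n2 - j2, n2 - j1
            arc_a = Arc(a1 % n, length, n)
            arc_b = Arc(b1 % n, length, n)
            if arc_a.overlaps(arc_b):
                continue  # self-palindrome or wrapped duplicate
            key = tuple(sorted([(arc_a.start, length), (arc_b.start, length)]))
            if key in seen:
                continue
            seen.add(key)
            first, second = sorted([arc_a, arc_b], key=lambda a: a.start)
            candidates.append(IRPair(first, second, ident))

    if not candidates:
        raise StructureNotFoundError("no inverted-repeat pair "
                                     f">= {min_len} bp at identity >= {min_identity}")
    candidates.sort(key=lambda p: (-p.length, p.copy1.start, p.copy2.start))
    return candidates[0]


def partition_genome(plastome: Plastome, irpair: IRPair) -> QuadripartitePartition:
    """Assign LSC (longer inter-IR arc), SSC (shorter), IRb (upstream of SSC)
    and IRa. Region lengths always sum to the genome length."""
    n = len(plastome)
    c1, c2 = irpair.copy1, irpair.copy2
    gap_after_c1 = (c2.start - c1.end) % n
    gap_after_c2 = (c1.start - c2.end) % n
    if gap_after_c1 == gap_after_c2:
        a = _build_partition(n, c1, c2, irpair.identity, ssc_after=1)
        b = _build_partition(n, c1, c2, irpair.identity, ssc_after=2)
        raise AmbiguousStructureError(
            "single-copy arcs have equal length; LSC/SSC ambiguous",
            assignments=[a, b])
    ssc_after = 1 if gap_after_c1 < gap_after_c2 else 2
    return _build_partition(n, c1, c2, irpair.identity, ssc_after)


def _build_partition(n, c1, c2, identity, ssc_after):
    if ssc_after == 1:
        irb, ira = c1, c2
    else:
        irb, ira = c2, c1
    ssc = Arc(irb.end, (ira.start - irb.end) % n, n)
    lsc = Arc(ira.end, (irb.start - ira.end) % n, n)
    return QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, n=n,
                                  identity=identity)


# ---------------------------------------------------------------------------
# Junction profiling and typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionSlot:
    """Genes at one junction: either an overlapping gene with the bp split
    across the junction, or the nearest gene on each side with distances."""

    junction: str
    position: int
    overlap: Optional[GeneFeature] = None
    split: Tuple[int, int] = (0, 0)  # bp of the overlapping gene left/right of the junction
    left: Optional[GeneFeature] = None
    left_dist: int = -1  # bp from gene end to junction
    right: Optional[GeneFeature] = None
    right_dist: int = -1  # bp from junction to gene start

    def flank_names(self) -> frozenset:
        names = set()
        if self.left is not None:
            names.add(self.left.name)
        if self.right is not None:
            names.add(self.right.name)
        return frozenset(names)


@dataclass
class JunctionProfile:
    slots: Dict[str, JunctionSlot] = field(default_factory=dict)

    def __getitem__(self, junction: str) -> JunctionSlot:
        return self.slots[junction]


def profile_junctions(plastome: Plastome, partition: QuadripartitePartition,
                      max_dist: int = 10_000) -> JunctionProfile:
    """For each of the four junctions report the overlapping gene (with its bp
    split) or the nearest annotated gene on each side with distances."""
    if not plastome.genes:
        raise ConsistencyError(f"{plastome.id}: no gene annotations")
    n = len(plastome)
    genes = [g for g in plastome.genes if g.kind != "intergenic"]
    prof = JunctionProfile()
    for jname, j in partition.junction_positions().items():
        over = None
        for g in genes:
            if g.start < j < g.end:
                over = g
                break
        if over is not None:
            prof.slots[jname] = JunctionSlot(
                junction=jname, position=j, overlap=over,
                split=(j - over.start, over.end - j))
            continue
        left = min(genes, key=lambda g: (j - g.end) % n, default=None)
        right = min(genes, key=lambda g: (g.start - j) % n, default=None)
        ld = (j - left.end) % n if left else -1
        rd = (right.start - j) % n if right else -1
        if left is not None and ld > max_dist:
            left, ld = None, -1
        if right is not None and rd > max_dist:
            right, rd = None, -1
        if left is None and right is None:
            warnings.warn(f"{plastome.id}: no gene within {max_dist} bp of {jname}")
        prof.slots[jname] = JunctionSlot(
            junction=jname, position=j, left=left, left_dist=ld,
            right=right, right_dist=rd)
    return prof


#: Marker genes the boundary classifier consults.
JUNCTION_MARKERS = ("trnN", "ndhF", "ycf1", "rps15", "trnR")


def classify_junction_type(profile: JunctionProfile, with_trace: bool = False):
    """Rule-based IR/SC boundary typing (types I-IV).

    I:   IRb/SSC between trnN and ndhF; SSC/IRa within ycf1 (or between ycf1
         and trnN - both sub-cases accepted and recorded).
    II:  IRb/SSC within ndhF; SSC/IRa between rps15 and ycf1 (ycf1 fully in IR).
    III: IRb/SSC between trnR and trnN; SSC/IRa between ycf1 and trnN.
    IV:  IRb/SSC between trnN and ycf1; SSC/IRa between ndhF and trnN
         (reverse-complemented SSC).
    """
    jsb = profile["IRb/SSC"]
    jsa = profile["SSC/IRa"]

    def result(label, trace):
        return (label, trace) if with_trace else label

    present = set()
    for slot in (jsb, jsa):
        present |= slot.flank_names()
        if slot.overlap is not None:
            present.add(slot.overlap.name)
    if not present & set(JUNCTION_MARKERS):
        return result("unclassified", "no junction marker genes annotated")

    def between(slot, a, b):
        return slot.overlap is None and slot.flank_names() == frozenset({a, b})

    def within(slot, a):
        return slot.overlap is not None and slot.overlap.name == a

    if between(jsb, "trnN", "ndhF"):
        if within(jsa, "ycf1"):
            return result("I", "SSC/IRa within ycf1")
        if between(jsa, "ycf1", "trnN"):
            return result("I", "SSC/IRa between ycf1 and trnN")
    if within(jsb, "ndhF") and between(jsa, "rps15", "ycf1"):
        return result("II", "IR expansion duplicating ycf1")
    if between(jsb, "trnR", "trnN") and between(jsa, "ycf1", "trnN"):
        return result("III", "SSC expansion including trnN")
    if between(jsb, "trnN", "ycf1") and between(jsa, "ndhF", "trnN"):
        return result("IV", "SSC reverse-complemented")
    return result("unclassified", f"no rule matched (IRb/SSC {sorted(jsb.flank_names())},"
                                  f" SSC/IRa {sorted(jsa.flank_names())})")


# ---------------------------------------------------------------------------
# Region-size correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    pair: Tuple[str, str]
    r: float
    r2: float
    p: float
    n: int
    note: str = ""


#: The six pairs of Fig.-2-style size correlations.
CORRELATION_PAIRS = (
    ("size", "LSC"), ("size", "SSC"), ("size", "IR"),
    ("LSC", "SSC"), ("LSC", "IR"), ("SSC", "IR"),
)


def region_size_correlations(partitions: Sequence[QuadripartitePartition]
                             ) -> List[CorrelationResult]:
    """Pearson r, R^2 and two-sided p (t distribution, df = n-2) between total
    genome size and LSC/SSC/IR lengths and between the regions themselves."""
    if len(partitions) < 3:
        raise ValueError("need at least 3 partitions")
    cols = {
        "size": np.array([p.n for p in partitions], dtype=float),
        "LSC": np.array([p.lsc.length for p in partitions], dtype=float),
        "SSC": np.array([p.ssc.length for p in partitions], dtype=float),
        "IR": np.array([p.irb.length for p in partitions], dtype=float),
    }
    out = []
    n = len(partitions)
    for a, b in CORRELATION_PAIRS:
        x, y = cols[a], cols[b]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(CorrelationResult((a, b), math.nan, math.nan, math.nan,
                                         n, note="zero variance"))
            continue
        r, p = stats.pearsonr(x, y)
        out.append(CorrelationResult((a, b), float(r), float(r) ** 2, float(p), n))
    return out
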