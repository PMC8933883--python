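"""Synthetic plastome families with known ground truth.

The generator emits circular genomes with the canonical quadripartite layout
LSC-IRb-SSC-IRa (IRa the exact reverse complement of IRb), junction-flanking
marker genes (rps19, rpl2, trnH, trnR, trnN, ndhF, rps15, ycf1 - with ycf1
spanning the SSC/IRa junction and its reverse-complement tail forming the
usual pseudogene fragment at the IRb end), planted SSRs and
dispersed/palindromic/tandem repeats, and a taxon family evolved along a known
tree under Jukes-Cantor substitutions with region-specific rate multipliers.

Two features keep the ground truth exact:

* no indels, so every tip stays positionally aligned with the ancestor;
* the IR evolves *concertedly* (one mutation stream applied to both copies),
  mimicking plastid gene conversion, so the planted IR pair stays an exact
  reverse-complement match and boundary recovery can be asserted to the base.

A handful of "junction anchor" sites (the single-copy bases flanking the IR
boundaries) are held invariant and constrained so that an inverted-repeat
match can never extend past a planted boundary by chance.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from ._seq import array_to_seq, random_seq, revcomp, seq_to_array
from .errors import ConfigError
from .io import GeneFeature, Plastome
from .quadripartite import Arc, QuadripartitePartition

_STOPS = {"TAA", "TAG", "TGA"}  # bacterial/plastid code 11

DEFAULT_TREE_8 = (
    "(((T1:0.01,T2:0.01):0.01,(T3:0.01,T4:0.01):0.01):0.01,"
    "((T5:0.01,T6:0.01):0.01,(T7:0.01,T8:0.01):0.01):0.01);"
)

DEFAULT_RATES = {
    "CDS": 0.8,
    "tRNA": 0.3,
    "rRNA": 0.3,
    "intergenic": 1.0,
    "IR": 0.15,
    "hotspots": {"atpH-atpI": 6.0, "trnS-trnG": 6.0, "psaC-ndhE": 6.0},
}

DEFAULT_GC = {"LSC": 0.338, "SSC": 0.286, "IR": 0.423}


@dataclass(frozen=True)
class PlannedSSR:
    motif: str
    copies: int
    region: str  # LSC / SSC / IR
    offset: int  # within region


@dataclass(frozen=True)
class PlannedRepeat:
    kind: str  # dispersed / palindromic / tandem
    length: int  # per-copy length (tandem: unit length)
    identity: float
    region1: str
    offset1: int
    region2: str = ""  # pair kinds only
    offset2: int = 0
    copies: int = 0  # tandem only


def _layout(lsc: int, ssc: int, ir: int) -> Tuple[list, Dict[str, int]]:
    """Gene layout entries (name, region, offset, length, strand, kind) plus
    derived parameters. Hotspot spacer widths scale with genome size."""
    big = lsc >= 50_000
    y_ir = min(4000, ir // 5)
    y_ssc = 1000 if ssc >= 8000 else ssc // 6
    y_ssc -= (y_ssc + y_ir) % 3
    hs1 = 1254 if big else 700    # atpH-atpI
    hs2 = 3412 if big else 900    # trnS-trnG
    hs3 = 1773 if big else 800    # psaC-ndhE
    ndhF_len = 2220 if big else 900
    rps15_gap = 1200 if big else 800

    L = []

    def lscf(frac):
        return int(lsc * frac)

    atpH = lscf(0.12)
    trnS = lscf(0.25)
    psaC = lscf(0.67)
    L += [
        ("trnH", "LSC", 10, 75, "+", "tRNA"),
        ("psbA", "LSC", lscf(0.01), 1062, "-", "CDS"),
        ("atpH", "LSC", atpH, 246, "+", "CDS"),
        ("atpI", "LSC", atpH + 246 + hs1, 744, "+", "CDS"),
        ("trnS", "LSC", trnS, 88, "+", "tRNA"),
        ("trnG", "LSC", trnS + 88 + hs2, 71, "+", "tRNA"),
        ("rbcL", "LSC", lscf(0.42), 1425, "+", "CDS"),
        ("matK", "LSC", lscf(0.53), 1500, "+", "CDS"),
        ("psaC", "LSC", psaC, 246, "+", "CDS"),
        ("ndhE", "LSC", psaC + 246 + hs3, 306, "+", "CDS"),
        ("accD", "LSC", lscf(0.80), 1464, "+", "CDS"),
        ("rps19", "LSC", lsc - 350, 279, "+", "CDS"),
        ("rpl2", "IR", 120, 1491, "-", "CDS"),
        ("trnR", "IR", ir - y_ir - 800, 72, "-", "tRNA"),
        ("trnN", "IR", ir - y_ir - 400, 72, "-", "tRNA"),
        ("ndhF", "SSC", 50, ndhF_len, "-", "CDS"),
        ("rpl32", "SSC", int(ssc * 0.17), 174, "+", "CDS"),
        ("trnL", "SSC", int(ssc * 0.24), 80, "+", "tRNA"),
        ("ndhG", "SSC", int(ssc * 0.40), 531 if big else 300, "+", "CDS"),
        ("ndhI", "SSC", int(ssc * 0.48), 501 if big else 300, "+", "CDS"),
        ("rps15", "SSC", ssc - y_ssc - rps15_gap - 273, 273, "+", "CDS"),
        # ycf1 spans the SSC/IRa junction: y_ssc bp in SSC + y_ir bp in IRa
        ("ycf1", "SSC", ssc - y_ssc, y_ssc + y_ir, "+", "CDS"),
    ]
    if big:
        L += [
            ("ccsA", "SSC", int(ssc * 0.26), 966, "+", "CDS"),
            ("ndhD", "SSC", int(ssc * 0.31), 1503, "+", "CDS"),
        ]
    params = {"y_ir": y_ir, "y_ssc": y_ssc}
    return L, params


def _default_ssr_plan(layout) -> List[PlannedSSR]:
    pos = {(name, region): (off, ln) for name, region, off, ln, _, _ in layout}
    atpH_end = sum(pos[("atpH", "LSC")])
    trnS_end = sum(pos[("trnS", "LSC")])
    psaC_end = sum(pos[("psaC", "LSC")])
    rbcL_end = sum(pos[("rbcL", "LSC")])
    trnL_end = sum(pos[("trnL", "SSC")])
    return [
        PlannedSSR("A", 12, "LSC", atpH_end + 100),
        PlannedSSR("AT", 7, "LSC", atpH_end + 300),
        PlannedSSR("AAG", 5, "LSC", atpH_end + 500),
        PlannedSSR("T", 11, "LSC", trnS_end + 100),
        PlannedSSR("CT", 6, "LSC", trnS_end + 300),
        PlannedSSR("AATC", 4, "LSC", trnS_end + 500),
        PlannedSSR("A", 10, "LSC", psaC_end + 100),
        PlannedSSR("TA", 6, "LSC", psaC_end + 300),
        PlannedSSR("AAT", 5, "LSC", psaC_end + 500),
        PlannedSSR("G", 10, "LSC", rbcL_end + 50),
        PlannedSSR("T", 10, "SSC", trnL_end + 150),
    ]


def _default_repeat_plan(layout) -> List[PlannedRepeat]:
    pos = {(name, region): (off, ln) for name, region, off, ln, _, _ in layout}
    accD_end = sum(pos[("accD", "LSC")])
    ndhI_end = sum(pos[("ndhI", "SSC")])
    return [
        PlannedRepeat("dispersed", 40, 1.0, "LSC", accD_end + 60, "LSC", accD_end + 250),
        PlannedRepeat("palindromic", 40, 1.0, "LSC", accD_end + 450, "LSC", accD_end + 600),
        PlannedRepeat("tandem", 9, 1.0, "SSC", ndhI_end + 100, copies=8),
    ]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic plastome family."""

    seed: int = 0
    lsc_len: int = 91_710
    ssc_len: int = 22_994
    ir_len: int = 25_601
    gc: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GC))
    gene_layout: Optional[list] = None  # (name, region, offset, length, strand, kind)
    ssr_plan: Optional[List[PlannedSSR]] = None
    repeat_plan: Optional[List[PlannedRepeat]] = None
    region_rates: Dict = field(default_factory=lambda: {
        k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_RATES.items()})
    tree: str = DEFAULT_TREE_8
    junction_edit: str = "none"  # none / typeII / typeIII / typeIV

    def __post_init__(self):
        if self.lsc_len <= self.ssc_len:
            raise ConfigError("LSC must be longer than SSC")
        if self.gene_layout is None:
            self.gene_layout, self._params = _layout(self.lsc_len, self.ssc_len, self.ir_len)
        else:
            self._params = {"y_ir": 0, "y_ssc": 0}
        if self.ssr_plan is None:
            self.ssr_plan = _default_ssr_plan(self.gene_layout)
        if self.repeat_plan is None:
            self.repeat_plan = _default_repeat_plan(self.gene_layout)
        for key, val in self.region_rates.items():
            vals = val.values() if isinstance(val, dict) else [val]
            if any(v <= 0 for v in vals):
                raise ConfigError(f"rate multiplier for {key} must be > 0")
        self._validate_layout()

    @classmethod
    def small(cls, seed: int = 0, **kw) -> "SynthConfig":
        """A ~30 kb genome with the same architecture; fast for simulations."""
        kw.setdefault("lsc_len", 14_000)
        kw.setdefault("ssc_len", 6_000)
        kw.setdefault("ir_len", 5_000)
        return cls(seed=seed, **kw)

    def region_len(self, region: str) -> int:
        return {"LSC": self.lsc_len, "SSC": self.ssc_len, "IR": self.ir_len}[region]

    def _validate_layout(self):
        by_region: Dict[str, list] = {}
        for name, region, off, ln, strand, kind in self.gene_layout:
            end = off + ln
            limit = self.region_len(region) + (self._params["y_ir"] if name == "ycf1" else 0)
            if off < 0 or end > limit:
                raise ConfigError(f"{name} does not fit inside {region}")
            by_region.setdefault(region, []).append((off, end, name))
        for ssr in self.ssr_plan:
            end = ssr.offset + len(ssr.motif) * ssr.copies
            if end > self.region_len(ssr.region):
                raise ConfigError(f"planted SSR {ssr.motif} does not fit in {ssr.region}")
            by_region.setdefault(ssr.region, []).append((ssr.offset, end, f"SSR:{ssr.motif}"))
        for rep in self.repeat_plan:
            spans = [(rep.region1, rep.offset1)]
            if rep.kind != "tandem":
                spans.append((rep.region2, rep.offset2))
            span_len = rep.length * (rep.copies if rep.kind == "tandem" else 1)
            for region, off in spans:
                if off + span_len > self.region_len(region):
                    raise ConfigError(f"planted {rep.kind} repeat does not fit in {region}")
                by_region.setdefault(region, []).append((off, off + span_len, rep.kind))
        for region, ivs in by_region.items():
            ivs.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ConfigError(f"planned features overlap in {region}: {n1} / {n2}")


@dataclass
class TruthTable:
    """Ground truth for one synthetic family, in emitted-genome coordinates."""

    config: SynthConfig
    partition: QuadripartitePartition
    junction_type: str
    genes: List[GeneFeature]
    ssrs: List[dict]      # {motif, copies, start, end}
    repeats: List[dict]   # {kind, length, identity, intervals, copies}
    guard_sites: List[int]
    tree: Optional[str] = None
    per_taxon: Dict[str, dict] = field(default_factory=dict)

    @property
    def hotspot_spacers(self) -> List[str]:
        return list(self.config.region_rates.get("hotspots", {}))


def _rng(seed: int, tag: str) -> np.random.Generator:
    """One stream per operation, independent of call order."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def _cds_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random in-frame CDS: ATG start, TAA stop, no internal stops, with the
    background GC composition."""
    assert length % 3 == 0 and length >= 6
    body = list(random_seq(rng, length - 6, gc))
    for c in range(0, len(body) - 2, 3):
        while "".join(body[c:c + 3]) in _STOPS:
            body[c:c + 3] = list(random_seq(rng, 3, gc))
    return "ATG" + "".join(body) + "TAA"


def _write(region: list, offset: int, s: str):
    region[offset:offset + len(s)] = list(s)


def _fix_ssr_flanks(region: list, start: int, end: int, unit: int,
                    rng: np.random.Generator):
    """Make a planted run maximal: the flanking bases must not extend it."""
    alphabet = "ACGT"
    if start > 0 and region[start - 1] == region[start + unit - 1]:
        region[start - 1] = alphabet[(alphabet.index(region[start - 1]) +
                                      1 + rng.integers(3)) % 4]
    if end < len(region) and region[end] == region[end - unit]:
        region[end] = alphabet[(alphabet.index(region[end]) +
                                1 + rng.integers(3)) % 4]


def _mutate_copy(seq: str, identity: float, rng: np.random.Generator) -> str:
    n_mut = int(round(len(seq) * (1.0 - identity)))
    if n_mut == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + 1 + rng.integers(3)) % 4]
    return "".join(out)


def _enforce_guards(seq: list, partition: QuadripartitePartition,
                    genes: List[GeneFeature], rng: np.random.Generator) -> List[int]:
    """Constrain the four single-copy bases flanking the IR boundaries so the
    IR match cannot extend past a planted boundary; returns the site list."""
    n = partition.n
    l = partition.irb.start
    s0, s1 = partition.ssc.start, (partition.ssc.start + partition.ssc.length)
    pairs = [((l - 1) % n, 0), (s0, (s1 - 1) % n)]
    genic = np.zeros(n, bool)
    for g in genes:
        genic[g.start:g.end] = True

    def comp(b):
        return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[b]

    sites = []
    for a, b in pairs:
        sites += [a, b]
        if seq[a] != comp(seq[b]):
            continue
        target = b if (genic[a] and not genic[b]) else (a if not genic[a] else b)
        other = a if target == b else b
        choices = [c for c in "ACGT" if c != comp(seq[other]) and c != seq[target]]
        seq[target] = choices[rng.integers(len(choices))]
    return sites


def build_ancestor(config: SynthConfig) -> Tuple[Plastome, TruthTable]:
    """Construct the ancestral genome LSC+IRb+SSC+IRa with planted features."""
    rng = _rng(config.seed, "ancestor")
    lsc = list(random_seq(rng, config.lsc_len, config.gc["LSC"]))
    irb = list(random_seq(rng, config.ir_len, config.gc["IR"]))
    ssc = list(random_seq(rng, config.ssc_len, config.gc["SSC"]))
    regions = {"LSC": lsc, "IR": irb, "SSC": ssc}
    y_ir, y_ssc = config._params["y_ir"], config._params["y_ssc"]

    # genes
    for name, region, off, ln, strand, kind in config.gene_layout:
        gc = config.gc[region if region != "IR" else "IR"]
        if name == "ycf1" and y_ir:
            s = _cds_seq(rng, ln, config.gc["SSC"])
            _write(ssc, config.ssc_len - y_ssc, s[:y_ssc])
            _write(irb, config.ir_len - y_ir, revcomp(s[y_ssc:]))
            continue
        s = _cds_seq(rng, ln, gc) if kind == "CDS" else random_seq(rng, ln, gc)
        _write(regions[region], off, s if strand == "+" else revcomp(s))

    # planted SSRs
    ssr_truth = []
    for ssr in config.ssr_plan:
        run = ssr.motif * ssr.copies
        reg = regions[ssr.region]
        _write(reg, ssr.offset, run)
        _fix_ssr_flanks(reg, ssr.offset, ssr.offset + len(run), len(ssr.motif), rng)
        base = {"LSC": 0, "IR": config.lsc_len,
                "SSC": config.lsc_len + config.ir_len}[ssr.region]
        ssr_truth.append({"motif": ssr.motif, "copies": ssr.copies,
                          "start": base + ssr.offset, "end": base + ssr.offset + len(run)})

    # planted dispersed/palindromic/tandem repeats
    rep_truth = []
    base_of = {"LSC": 0, "IR": config.lsc_len, "SSC": config.lsc_len + config.ir_len}
    for rep in config.repeat_plan:
        if rep.kind == "tandem":
            unit = random_seq(rng, rep.length, 0.45)
            arr = _mutate_copy(unit * rep.copies, rep.identity, rng)
            _write(regions[rep.region1], rep.offset1, arr)
            g = base_of[rep.region1] + rep.offset1
            rep_truth.append({"kind": "tandem", "length": len(arr),
                              "identity": rep.identity, "copies": rep.copies,
                              "unit_len": rep.length, "intervals": [(g, g + len(arr))]})
        else:
            s1 = random_seq(rng, rep.length, 0.45)
            s2 = revcomp(s1) if rep.kind == "palindromic" else s1
            s2 = _mutate_copy(s2, rep.identity, rng)
            _write(regions[rep.region1], rep.offset1, s1)
            _write(regions[rep.region2], rep.offset2, s2)
            g1 = base_of[rep.region1] + rep.offset1
            g2 = base_of[rep.region2] + rep.offset2
            rep_truth.append({"kind": rep.kind, "length": rep.length,
                              "identity": rep.identity,
                              "intervals": [(g1, g1 + rep.length), (g2, g2 + rep.length)]})

    l, i, s = config.lsc_len, config.ir_len, config.ssc_len
    n = l + s + 2 * i
    partition = QuadripartitePartition(
        lsc=Arc(0, l, n), irb=Arc(l, i, n), ssc=Arc(l + i, s, n),
        ira=Arc(l + i + s, i, n), n=n)

    genes = _global_genes(config)
    core = lsc + irb + ssc
    guard_sites = _enforce_guards(core, partition, genes, rng)
    seq = "".join(core) + revcomp("".join(core[l:l + i]))

    truth = TruthTable(config=config, partition=partition, junction_type="I",
                       genes=genes, ssrs=ssr_truth, repeats=rep_truth,
                       guard_sites=guard_sites, tree=config.tree)
    return Plastome(id="ancestor", seq=seq, circular=True, genes=genes), truth


def _global_genes(config: SynthConfig) -> List[GeneFeature]:
    l, i, s = config.lsc_len, config.ir_len, config.ssc_len
    y_ir, y_ssc = config._params["y_ir"], config._params["y_ssc"]
    genes = []
    for name, region, off, ln, strand, kind in config.gene_layout:
        if name == "ycf1" and y_ir:
            genes.append(GeneFeature("ycf1", l + i + s - y_ssc, l + i + s + y_ir, "+", "CDS"))
            continue
        if region == "LSC":
            genes.append(GeneFeature(name, off, off + ln, strand, kind))
        elif region == "SSC":
            genes.append(GeneFeature(name, l + i + off, l + i + off + ln, strand, kind))
        else:  # IR: annotate both copies
            genes.append(GeneFeature(name, l + off, l + off + ln, strand, kind))
            flip = "-" if strand == "+" else "+"
            a0 = l + i + s + (i - off - ln)
            genes.append(GeneFeature(name, a0, a0 + ln, flip, kind))
    genes.sort(key=lambda g: (g.start, g.end))
    return genes


# ---------------------------------------------------------------------------
# Junction edits
# ---------------------------------------------------------------------------

def apply_junction_edit(plastome: Plastome, truth: TruthTable, kind: str
                        ) -> Tuple[Plastome, TruthTable]:
    """Rewrite a type-I genome into a type II/III boundary architecture, or
    reverse-complement the SSC (type IV, an involution)."""
    if kind == "typeII":
        return _edit_type2(plastome, truth)
    if kind == "typeIII":
        return _edit_type3(plastome, truth)
    if kind == "typeIV":
        return _edit_type4(plastome, truth)
    raise ConfigError(f"unknown junction edit {kind!r}")


def _layout_pos(config, name, region):
    for nm, rg, off, ln, _, _ in config.gene_layout:
        if nm == name and rg == region:
            return off, ln
    raise ConfigError(f"layout lacks {name} in {region}")


def _remap_features(feats, mapper):
    out = []
    for f in feats:
        m = mapper(f)
        if m is not None:
            out.extend(m if isinstance(m, list) else [m])
    out.sort(key=lambda g: (g.start, g.end))
    return out


def _edit_type2(plastome, truth):
    """IR expansion into the SSC: both IRs grow, ycf1 becomes fully duplicated,
    the IRb/SSC junction lands inside ndhF and SSC/IRa between rps15 and ycf1."""
    cfg = truth.config
    l, i, s = cfg.lsc_len, cfg.ir_len, cfg.ssc_len
    y_ir, y_ssc = cfg._params["y_ir"], cfg._params["y_ssc"]
    seq = plastome.seq
    L, B, S = seq[:l], seq[l:l + i], seq[l + i:l + i + s]
    ndhF_off, ndhF_len = _layout_pos(cfg, "ndhF", "SSC")
    rps15_off, rps15_len = _layout_pos(cfg, "rps15", "SSC")
    rps15_end = rps15_off + rps15_len
    dB = ndhF_off + ndhF_len // 2
    gap = (s - y_ssc) - rps15_end
    dA = s - (rps15_end + gap // 2)
    if s - dA - dB <= 0:
        raise ConfigError("type II expansion would erase the SSC")

    s_pre, s_suf = S[:dB], S[s - dA:]
    new_irb = B + revcomp(s_suf) + s_pre
    new_ssc = S[dB:s - dA]
    new_ira = revcomp(new_irb)
    new_seq = L + new_irb + new_ssc + new_ira
    n = len(new_seq)
    q = l + len(new_irb) + len(new_ssc)  # == l + i + s

    def map_pos(p):
        """ancestor coordinate -> edited coordinate (single-copy + B regions)."""
        if p < l + i:
            return p
        if p < l + i + s - dA:  # S_pre and S_mid are contiguous after the insert
            return p + dA
        return None

    def mapper(f):
        if f.name == "ycf1":
            return [GeneFeature("ycf1", l + i - y_ir, l + i + y_ssc, "-", "CDS"),
                    GeneFeature("ycf1", q + dB + dA - y_ssc, q + dB + dA + y_ir, "+", "CDS")]
        if f.start >= l + i + s:  # IRa mirror copies
            off = f.start - (l + i + s)
            return replace(f, start=q + dB + dA + off, end=q + dB + dA + off + len(f))
        a, b = map_pos(f.start), map_pos(f.end - 1)
        if a is None or b is None:
            return None
        return replace(f, start=a, end=b + 1)

    genes = _remap_features(plastome.genes, mapper)
    partition = QuadripartitePartition(
        lsc=Arc(0, l, n), irb=Arc(l, i + dA + dB, n),
        ssc=Arc(l + i + dA + dB, s - dA - dB, n), ira=Arc(q, i + dA + dB, n), n=n)

    new_truth = _edited_truth(truth, partition, "II", genes, map_pos)
    return _finalize_edit(plastome, new_seq, genes, partition, new_truth)


def _edit_type3(plastome, truth):
    """IR contraction / SSC expansion: trnN moves into the SSC (junction
    between trnR and trnN) and ycf1 ends up fully inside the SSC with the
    SSC/IRa junction between ycf1 and trnN."""
    cfg = truth.config
    rng = _rng(cfg.seed, "junction_edit")
    l, i, s = cfg.lsc_len, cfg.ir_len, cfg.ssc_len
    y_ir, y_ssc = cfg._params["y_ir"], cfg._params["y_ssc"]
    seq = plastome.seq
    L, B, S, A = seq[:l], seq[l:l + i], seq[l + i:l + i + s], seq[l + i + s:]
    cut = i - y_ir - 150
    tn_off, tn_len = _layout_pos(cfg, "trnN", "IR")
    if cut <= tn_off + tn_len:
        raise ConfigError("type III contraction would erase the SSC-side trnN")
    C = B[:cut]
    d1 = random_seq(rng, 60, 0.3) + B[tn_off:tn_off + tn_len] + random_seq(rng, 40, 0.3)
    sp2 = random_seq(rng, 50, 0.3)
    new_seq = L + C + d1 + S + A[:y_ir] + sp2 + revcomp(C)
    n = len(new_seq)
    s_base = l + cut + len(d1)          # where S now starts
    a_base = s_base + s + y_ir + len(sp2)  # where the new IRa starts
    new_ssc_len = a_base - (l + cut)

    def map_pos(p):
        if p < l + cut:
            return p  # LSC + retained IR core
        if l + i <= p < l + i + s:
            return p - (l + i) + s_base
        return None

    def mapper(f):
        if f.name == "ycf1":
            return GeneFeature("ycf1", s_base + s - y_ssc, s_base + s + y_ir, "+", "CDS")
        if f.start >= l + i + s:  # old IRa mirrors: rebuild from the core below
            return None
        if l <= f.start < l + i:  # B copy
            if f.end > l + cut:
                return None
            if f.name == "trnN":
                return None  # SSC-side copy left unannotated (degraded)
            return f
        a, b = map_pos(f.start), map_pos(f.end - 1)
        if a is None or b is None:
            return None
        return replace(f, start=a, end=b + 1)

    genes = _remap_features(plastome.genes, mapper)
    # annotated genes of the new IRa = mirrors of the retained core, trnN included
    for nm, rg, off, ln, strand, kd in cfg.gene_layout:
        if rg != "IR" or off + ln > cut:
            continue
        flip = "-" if strand == "+" else "+"
        a0 = a_base + (cut - off - ln)
        genes.append(GeneFeature(nm, a0, a0 + ln, flip, kd))
    # the planted SSC-side trnN inside d1
    genes.append(GeneFeature("trnN", l + cut + 60, l + cut + 60 + tn_len, "-", "tRNA"))
    genes.sort(key=lambda g: (g.start, g.end))

    partition = QuadripartitePartition(
        lsc=Arc(0, l, n), irb=Arc(l, cut, n),
        ssc=Arc(l + cut, new_ssc_len, n), ira=Arc(a_base, cut, n), n=n)
    new_truth = _edited_truth(truth, partition, "III", genes, map_pos)
    return _finalize_edit(plastome, new_seq, genes, partition, new_truth)


def _edit_type4(plastome, truth):
    """Reverse-complement the SSC segment in place (an involution)."""
    part = truth.partition
    s0, s1 = part.ssc.start, part.ssc.start + part.ssc.length
    seq = plastome.seq
    new_seq = seq[:s0] + revcomp(seq[s0:s1]) + seq[s1:]

    def flipped(f):
        return replace(f, start=s0 + (s1 - f.end), end=s0 + (s1 - f.start),
                       strand="-" if f.strand == "+" else "+")

    genes = []
    for f in plastome.genes:
        if f.end <= s0 or f.start >= s1:
            genes.append(f)
        elif s0 <= f.start and f.end <= s1:
            genes.append(flipped(f))
        elif f.start < s1 <= f.end:
            # SSC/IRa-spanning gene (ycf1): keep the SSC part as the named
            # fragment, drop the stranded IR part (pseudogenised by the flip)
            genes.append(flipped(replace(f, end=s1)))
        else:
            genes.append(flipped(replace(f, start=s0)))
    genes = _merge_contiguous(sorted(genes, key=lambda g: (g.start, g.end)))

    label = "IV" if truth.junction_type != "IV" else "I"
    new_ssrs = []
    for t in truth.ssrs:
        if s0 <= t["start"] and t["end"] <= s1:
            new_ssrs.append({"motif": revcomp(t["motif"]), "copies": t["copies"],
                             "start": s0 + (s1 - t["end"]), "end": s0 + (s1 - t["start"])})
        else:
            new_ssrs.append(dict(t))
    new_reps = []
    for t in truth.repeats:
        ivs = []
        for a, b in t["intervals"]:
            if s0 <= a and b <= s1:
                ivs.append((s0 + (s1 - b), s0 + (s1 - a)))
            else:
                ivs.append((a, b))
        new_reps.append({**t, "intervals": ivs})

    new_truth = TruthTable(config=truth.config, partition=part,
                           junction_type=label, genes=genes, ssrs=new_ssrs,
                           repeats=new_reps, guard_sites=truth.guard_sites,
                           tree=truth.tree)
    return (Plastome(id=plastome.id, seq=new_seq, circular=True, genes=genes),
            new_truth)


def _merge_contiguous(genes):
    out = []
    for g in genes:
        if out and out[-1].name == g.name and out[-1].strand == g.strand \
                and out[-1].kind == g.kind and out[-1].end == g.start:
            out[-1] = replace(out[-1], end=g.end)
        else:
            out.append(g)
    return out


def _edited_truth(truth, partition, label, genes, map_pos):
    ssrs = []
    for t in truth.ssrs:
        a, b = map_pos(t["start"]), map_pos(t["end"] - 1)
        if a is not None and b is not None and (b + 1 - a) == (t["end"] - t["start"]):
            ssrs.append({**t, "start": a, "end": b + 1})
    reps = []
    for t in truth.repeats:
        ivs = []
        ok = True
        for p, q in t["intervals"]:
            a, b = map_pos(p), map_pos(q - 1)
            if a is None or b is None:
                ok = False
                break
            ivs.append((a, b + 1))
        if ok:
            reps.append({**t, "intervals": ivs})
    return TruthTable(config=truth.config, partition=partition,
                      junction_type=label, genes=genes, ssrs=ssrs,
                      repeats=reps, guard_sites=[], tree=truth.tree)


def _finalize_edit(plastome, new_seq, genes, partition, new_truth):
    rng = _rng(new_truth.config.seed, "guards")
    core = list(new_seq[:partition.ira.start])
    guard_sites = _enforce_guards(core, partition, genes, rng)
    irb0, irb1 = partition.irb.start, partition.irb.start + partition.irb.length
    seq = "".join(core) + revcomp("".join(core[irb0:irb1]))
    new_truth.guard_sites = guard_sites
    return (Plastome(id=plastome.id, seq=seq, circular=True, genes=genes),
            new_truth)


# ---------------------------------------------------------------------------
# Evolution along a tree
# ---------------------------------------------------------------------------

def site_rates(truth: TruthTable) -> np.ndarray:
    """Per-site substitution-rate multipliers over the whole genome."""
    cfg = truth.config
    rates = cfg.region_rates
    for key in ("CDS", "tRNA", "rRNA", "intergenic", "IR"):
        if key not in rates:
            raise ConfigError(f"region_rates missing multiplier for {key!r}")
    n = truth.partition.n
    r = np.full(n, float(rates["intergenic"]))
    for g in truth.genes:
        if g.kind in ("CDS", "tRNA", "rRNA"):
            r[g.start:g.end] = rates[g.kind]
    for name, (a, b) in spacer_intervals(truth).items():
        if name in rates.get("hotspots", {}):
            r[a:b] = rates["hotspots"][name]
    for arc in (truth.partition.irb, truth.partition.ira):
        for a, b in arc.intervals():
            r[a:b] *= rates["IR"]
    # planted SSRs (and one flanking base) are held fixed: without a slippage
    # process, substitution would simply erode them, whereas real
    # microsatellite loci persist across related taxa
    for t in truth.ssrs:
        r[max(0, t["start"] - 1):min(n, t["end"] + 1)] = 0.0
    r[truth.guard_sites] = 0.0  # junction anchors stay fixed
    return r


def spacer_intervals(truth: TruthTable) -> Dict[str, Tuple[int, int]]:
    """Intergenic intervals named 'A-B' between consecutive annotated genes."""
    out = {}
    genes = sorted(truth.genes, key=lambda g: g.start)
    for g1, g2 in zip(genes, genes[1:]):
        if g2.start > g1.end:
            out.setdefault(f"{g1.name}-{g2.name}", (g1.end, g2.start))
    return out


def evolve_family(ancestor: Plastome, truth: TruthTable,
                  tree: Optional[str] = None, region_rates: Optional[dict] = None,
                  seed: Optional[int] = None
                  ) -> Tuple[List[Plastome], TruthTable]:
    """Evolve the ancestor along a tree under per-site Jukes-Cantor
    substitution, IRs evolving concertedly so IRa stays the exact reverse
    complement of IRb. No indels: tips stay positionally aligned."""
    cfg = truth.config
    if region_rates is not None:
        truth = replace_rates(truth, region_rates)
    newick = tree if tree is not None else (truth.tree or cfg.tree)
    seed = cfg.seed if seed is None else seed
    t = dendropy.Tree.get(data=newick, schema="newick")
    if len(t.leaf_nodes()) < 3:
        raise ConfigError("tree must have at least 3 tips")

    part = truth.partition
    assert (part.ira.start + part.ira.length) % part.n == 0, "IRa must be terminal"
    core_len = part.ira.start
    rates = site_rates(truth)[:core_len]
    irb0, irb1 = part.irb.start, part.irb.start + part.irb.length
    codon_idx = _cds_codon_index(truth, core_len)

    anc = seq_to_array(ancestor.seq[:core_len])
    tips: Dict[str, np.ndarray] = {}
    counter = [0]

    def walk(node, state):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            if bl < 0:
                raise ConfigError("negative branch length")
            counter[0] += 1
            rng = _rng(seed, f"branch{counter[0]}")
            child_state = state.copy()
            if bl > 0:
                p = 0.75 * (1.0 - np.exp(-4.0 * bl * rates / 3.0))
                hit = np.nonzero(rng.random(core_len) < p)[0]
                if hit.size:
                    child_state[hit] = (child_state[hit] + 1 +
                                        rng.integers(0, 3, hit.size)).astype(np.uint8) % 4
                    _revert_nonsense(child_state, state, codon_idx)
            if child.is_leaf():
                tips[child.taxon.label] = child_state
            else:
                walk(child, child_state)

    walk(t.seed_node, anc)

    plastomes = []
    truth.tree = newick
    truth.per_taxon = {}
    for label in sorted(tips):
        core = array_to_seq(tips[label])
        seq = core + revcomp(core[irb0:irb1])
        p = Plastome(id=label, seq=seq, circular=True, genes=list(ancestor.genes))
        plastomes.append(p)
        truth.per_taxon[label] = {"intact_ssrs": _intact_ssrs(seq, truth.ssrs)}
    return plastomes, truth


# stop codons of the plastid/bacterial code as base-4 ids (A=0 C=1 G=2 T=3),
# read on the coding strand
_STOP_IDS = np.array([int("".join(str("ACGT".index(b)) for b in s), 4)
                      for s in sorted(_STOPS)])


def _cds_codon_index(truth: TruthTable, core_len: int) -> list:
    """(n_codons x 3 position array, coding-strand flag) per CDS gene fully
    inside the single-copy+IRb core. Junction-spanning genes (ycf1) are
    excluded: their IR portion is regenerated from the concerted IR copy."""
    out = []
    for g in truth.genes:
        if g.kind != "CDS" or g.end > core_len or len(g) % 3:
            continue
        pos = np.arange(g.start, g.end)
        if g.strand == "-":
            pos = pos[::-1]
        out.append((pos.reshape(-1, 3), g.strand == "+"))
    return out


def _revert_nonsense(state: np.ndarray, parent: np.ndarray, codon_idx: list):
    """Purifying selection against nonsense changes: any codon that became an
    internal stop on this branch is reverted to its parent state."""
    for pos, forward in codon_idx:
        cod = state[pos]
        if not forward:
            cod = 3 - cod  # complement in base-4 encoding
        ids = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
        bad = np.isin(ids[:-1], _STOP_IDS)  # terminal stop codon is fine
        if bad.any():
            hit = pos[:-1][bad].ravel()
            state[hit] = parent[hit]


def replace_rates(truth: TruthTable, region_rates: dict) -> TruthTable:
    import copy
    t = copy.copy(truth)
    t.config = copy.copy(truth.config)
    t.config.region_rates = region_rates
    return t


def _intact_ssrs(seq: str, planted: List[dict]) -> List[dict]:
    out = []
    for t in planted:
        u = len(t["motif"])
        a, b = t["start"], t["end"]
        if seq[a:b] != t["motif"] * t["copies"]:
            continue
        if a >= u and seq[a - 1] == seq[a + u - 1]:
            continue  # extendable leftward: coordinates shifted
        if b + 1 <= len(seq) and b < len(seq) and seq[b] == seq[b - u]:
            continue
        out.append(dict(t))
    return out


def make_family(config: SynthConfig) -> Tuple[Plastome, List[Plastome], TruthTable]:
    """Convenience: ancestor -> optional junction edit -> evolved family."""
    anc, truth = build_ancestor(config)
    if config.junction_edit != "none":
        anc, truth = apply_junction_edit(anc, truth, config.junction_edit)
    fam, truth = evolve_family(anc, truth)
    return anc, fam, truth
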