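"""Pairwise Ka/Ks screen (Nei & Gojobori 1986 counting, NG86).

Synonymous/nonsynonymous site counts use fractional synonymous potential per
codon position (mutations creating stop codons count as nonsynonymous, so
every counted codon contributes exactly 3 sites); differences average over
all minimal substitution pathways per codon, excluding pathways that pass
through a stop codon when any stop-free pathway exists. Proportions are
Jukes-Cantor corrected, d = -(3/4) ln(1 - 4p/3). The plastid (bacterial)
genetic code, NCBI table 11, is the default.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._seq import jc69_distance
from .errors import PlastokitError, SaturationError
from .diversity import RegionAlignment

_BASES = "ACGT"


class FrameError(PlastokitError):
    """Sequence length not a multiple of 3 or internal stop codon."""


def _code(table_id: int):
    t = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(t.forward_table)
    stops = set(t.stop_codons)
    return fwd, stops


def _syn_fraction(codon: str, fwd: Dict[str, str], stops) -> float:
    """Fractional number of synonymous sites in a codon (0..3)."""
    aa = fwd[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in stops and fwd[alt] == aa:
                s += 1 / 3
    return s


def _pathway_diffs(c1: str, c2: str, fwd, stops) -> Tuple[float, float]:
    """(syn, nonsyn) differences for one codon pair, averaged over minimal
    pathways; stop-passing pathways excluded when avoidable."""
    pos = [p for p in range(3) if c1[p] != c2[p]]
    if not pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(pos):
        cur = c1
        steps = []
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in stops:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [st for blocked, st in paths if not blocked] or [st for _, st in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a in stops or b in stops:
                nd += 1  # stop-involving step (only on unavoidable pathways)
            elif fwd[a] == fwd[b]:
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


@dataclass(frozen=True)
class KaKsRecord:
    gene: str
    taxon_pair: Tuple[str, str]
    ka: float
    ks: float
    omega: Optional[float]       # None when ks == 0 (undefined)
    n_sites: float               # nonsynonymous sites
    s_sites: float               # synonymous sites
    n_codons: int                # codons actually counted
    sd: float                    # synonymous differences
    nd: float                    # nonsynonymous differences


def ng86_kaks(cds_a: str, cds_b: str, genetic_code: int = 11,
              gene: str = "?", taxa: Tuple[str, str] = ("a", "b")
              ) -> KaKsRecord:
    """NG86 Ka/Ks for one pair of in-frame CDS sequences.

    Codons containing a gap or N in either sequence are excluded pairwise; a
    terminal stop codon is dropped; an internal stop raises naming the codon.
    """
    fwd, stops = _code(genetic_code)
    if len(cds_a) != len(cds_b):
        raise FrameError(f"{gene}: sequences differ in length")
    if len(cds_a) % 3:
        raise FrameError(f"{gene}: length {len(cds_a)} not a multiple of 3")
    n_codons_total = len(cds_a) // 3
    pairs = []
    for c in range(n_codons_total):
        c1 = cds_a[3 * c:3 * c + 3].upper()
        c2 = cds_b[3 * c:3 * c + 3].upper()
        if set(c1 + c2) - set(_BASES):
            continue  # gap/N masking
        is_stop1, is_stop2 = c1 in stops, c2 in stops
        if is_stop1 or is_stop2:
            if c == n_codons_total - 1:
                continue  # terminal stop: excluded from site counts
            raise FrameError(f"{gene}: internal stop codon at codon {c + 1}")
        pairs.append((c1, c2))
    S = N = Sd = Nd = 0.0
    for c1, c2 in pairs:
        s_c = 0.5 * (_syn_fraction(c1, fwd, stops) + _syn_fraction(c2, fwd, stops))
        S += s_c
        N += 3 - s_c
        sd, nd = _pathway_diffs(c1, c2, fwd, stops)
        Sd += sd
        Nd += nd
    if not pairs:
        raise FrameError(f"{gene}: no comparable codons")
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    try:
        ks = jc69_distance(ps) if ps > 0 else 0.0
        ka = jc69_distance(pn) if pn > 0 else 0.0
    except ValueError as e:
        raise SaturationError(f"{gene}: {e}") from None
    omega = (ka / ks) if ks > 0 else None
    return KaKsRecord(gene=gene, taxon_pair=tuple(taxa), ka=float(ka),
                      ks=float(ks), omega=omega, n_sites=float(N),
                      s_sites=float(S), n_codons=len(pairs),
                      sd=float(Sd), nd=float(Nd))


def gene_selection_screen(gene_alignments: Dict[str, RegionAlignment],
                          genetic_code: int = 11) -> pd.DataFrame:
    """Mean pairwise omega per gene over all taxon pairs with defined omega;
    genes with mean omega > 1 are flagged, genes with no defined omega are NA."""
    rows = []
    for gene, aln in gene_alignments.items():
        if aln.length % 3:
            raise FrameError(f"{gene}: alignment length {aln.length} not in frame")
        omegas = []
        kas, kss = [], []
        n = len(aln.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                rec = ng86_kaks(aln.rows[i].replace("-", "N"),
                                aln.rows[j].replace("-", "N"),
                                genetic_code, gene,
                                (aln.taxa[i], aln.taxa[j]))
                kas.append(rec.ka)
                kss.append(rec.ks)
                if rec.omega is not None:
                    omegas.append(rec.omega)
        mean_omega = float(np.mean(omegas)) if omegas else np.nan
        rows.append({"gene": gene, "n_pairs": n * (n - 1) // 2,
                     "n_defined": len(omegas),
                     "mean_ka": float(np.mean(kas)),
                     "mean_ks": float(np.mean(kss)),
                     "mean_omega": mean_omega,
                     "positive_selection": bool(omegas) and mean_omega > 1.0})
    return (pd.DataFrame(rows, columns=["gene", "n_pairs", "n_defined",
                                        "mean_ka", "mean_ks", "mean_omega",
                                        "positive_selection"])
            .sort_values("gene").reset_index(drop=True))
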