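"""Highly-variable-region (HVR) selection and DNA-barcode evaluation.

A region is nominated as a barcode candidate when its nucleotide diversity
exceeds a threshold (strictly; default Pi > 0.17) AND it carries at least a
minimum number of SSRs (default 3) in at least one focal taxon. Candidates
(single or concatenated) are evaluated by building an NJ + bootstrap tree and
comparing it against a reference tree: the discrimination success ratio is
100 x the fraction of non-trivial reference splits recovered by the barcode
tree, so the reference alignment itself always scores 100.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .diversity import DiversityRecord, RegionAlignment
from .errors import ConsistencyError
from .phylo import bootstrap_support, shared_split_fraction

#: Spellings treated as the same spacer.
SPACER_ALIASES = {"trnN-trnF": "trnN-ndhF"}


def _norm(name: str) -> str:
    return SPACER_ALIASES.get(name, name)


@dataclass(frozen=True)
class MarkerCandidate:
    name: str
    pi: float
    ssr_count_max: int
    selected_by: str


def select_hvrs(diversity_records: Sequence[DiversityRecord],
                ssr_summaries, pi_threshold: float = 0.17,
                min_ssr: int = 3) -> List[MarkerCandidate]:
    """Regions with pi strictly above the threshold and >= min_ssr SSRs in at
    least one focal taxon.

    ``ssr_summaries`` maps focal taxon -> SSRSummary (or is a sequence of
    summaries); SSR counts are read from each summary's per-locus table.
    """
    if isinstance(ssr_summaries, dict):
        summaries = list(ssr_summaries.values())
    else:
        summaries = list(ssr_summaries)
    counts: Dict[str, int] = {}
    for summ in summaries:
        for locus, row in summ.locus_counts.iterrows():
            key = _norm(locus)
            counts[key] = max(counts.get(key, 0), int(row["n_ssrs"]))
    by_name: Dict[str, DiversityRecord] = {}
    for r in diversity_records:
        by_name[_norm(r.name)] = r
    orphans = [k for k, v in counts.items()
               if v >= min_ssr and "-" in k and k not in by_name]
    if orphans and not by_name:
        raise ConsistencyError(f"no shared region names; orphans: {orphans}")
    out = []
    for name, rec in sorted(by_name.items()):
        c = counts.get(name, 0)
        if rec.pi > pi_threshold and c >= min_ssr:
            out.append(MarkerCandidate(
                name=name, pi=rec.pi, ssr_count_max=c,
                selected_by=f"pi={rec.pi:.3f}>{pi_threshold} and "
                            f"ssr_max={c}>={min_ssr}"))
    return out


def alignment_stats(alignment: RegionAlignment) -> Tuple[int, int, int]:
    """(alignment length, variable sites, parsimony-informative sites).

    Variable: >= 2 distinct non-gap/non-N states. Informative: >= 2 states
    each present in >= 2 taxa (gaps/N are not states).
    """
    if len(alignment.rows) < 4:
        raise ValueError("alignment stats need >= 4 rows")
    L = alignment.length
    variable = informative = 0
    for c in range(L):
        counts: Dict[str, int] = {}
        for row in alignment.rows:
            ch = row[c]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
    return L, variable, informative


def combine_markers(alignments: Sequence[RegionAlignment],
                    names: Optional[Sequence[str]] = None) -> RegionAlignment:
    """Column-wise concatenation in the given order; taxa are intersected
    (dropped taxa recorded on the result); combined length = sum of parts."""
    if not alignments:
        raise ValueError("nothing to combine")
    names = list(names) if names else [a.name for a in alignments]
    taxa_sets = [set(a.taxa) for a in alignments]
    shared = sorted(set.intersection(*taxa_sets))
    if not shared:
        raise ConsistencyError("combined markers share no taxa")
    dropped = sorted(set.union(*taxa_sets) - set(shared))
    rows = []
    boundaries = []
    offset = 0
    for a in alignments:
        boundaries.append((offset, offset + a.length))
        offset += a.length
    for t in shared:
        parts = []
        for a in alignments:
            parts.append(a.rows[a.taxa.index(t)])
        rows.append("".join(parts))
    out = RegionAlignment(name="+".join(names),
                          cls="combined", taxa=shared, rows=rows)
    out.boundaries = boundaries
    out.dropped_taxa = dropped
    return out


@dataclass(frozen=True)
class BarcodeEvaluation:
    marker: str
    aln_length: int
    variable_sites: int
    variable_pct: float
    informative_sites: int
    informative_pct: float
    n_supported: int       # internal edges with bootstrap support > threshold
    discrimination: float  # 100 x shared_split_fraction vs the reference tree
    rf: int
    n_boot: int


def evaluate_barcode(alignment: RegionAlignment, ref_tree, n_boot: int,
                     seed: int, support_threshold: float = 75.0,
                     model: str = "JC69") -> BarcodeEvaluation:
    """Build the barcode's NJ + bootstrap tree and score it against the
    reference tree. The support count uses a strict '> threshold' rule."""
    st = bootstrap_support(alignment, n_boot, seed, model=model)
    comp = shared_split_fraction(st.tree, ref_tree)
    L, var, inf = alignment_stats(alignment)
    return BarcodeEvaluation(
        marker=alignment.name, aln_length=L,
        variable_sites=var, variable_pct=100.0 * var / L,
        informative_sites=inf, informative_pct=100.0 * inf / L,
        n_supported=st.n_supported(support_threshold),
        discrimination=100.0 * comp.fraction, rf=comp.rf, n_boot=n_boot)


def marker_ranking_table(evaluations: Sequence[BarcodeEvaluation]
                         ) -> pd.DataFrame:
    """Ranked marker table: discrimination descending, ties broken by the
    number of well-supported edges."""
    if not evaluations:
        raise ValueError("no evaluations")
    df = pd.DataFrame([{
        "marker": e.marker,
        "aln_length_bp": e.aln_length,
        "variable_sites": f"{e.variable_sites} ({e.variable_pct:.1f})",
        "informative_sites": f"{e.informative_sites} ({e.informative_pct:.1f})",
        "n_bootstrap_gt_75": e.n_supported,
        "discrimination_pct": round(e.discrimination, 1),
    } for e in evaluations])
    return (df.sort_values(["discrimination_pct", "n_bootstrap_gt_75"],
                           ascending=[False, False], kind="mergesort")
            .reset_index(drop=True))
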