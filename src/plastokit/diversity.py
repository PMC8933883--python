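"""Per-region nucleotide diversity (Pi).

Annotated plastomes are partitioned into shared gene-coding regions and
intergenic spacers (named ``A-B`` after their flanking genes in genome
order). Each region is aligned - either with the built-in progressive
aligner (meant for toy/test scale) or by ingesting an externally produced
alignment - and Nei's nucleotide diversity

    pi = sum_{i<j} d_ij / C(n, 2)

is computed per region, where d_ij is the per-site difference proportion
between rows i and j over the retained columns. Columns containing a gap or N
are removed before computing (complete deletion, the DnaSP default); pairwise
deletion is available as a switch.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from Bio import SeqIO

from ._seq import seq_to_array
from .errors import ConsistencyError, FormatError, NoSitesError
from .io import Plastome


@dataclass
class RegionAlignment:
    name: str
    cls: str                    # coding / noncoding
    taxa: List[str]
    rows: List[str]             # equal-length aligned sequences, gap '-'

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError(f"{self.name}: need >= 2 sequences")
        if len({len(r) for r in self.rows}) != 1:
            raise FormatError(f"{self.name}: aligned rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def degap(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass(frozen=True)
class DiversityRecord:
    name: str
    cls: str
    pi: float
    n_taxa: int
    n_sites_used: int


# ---------------------------------------------------------------------------
# Shared region extraction
# ---------------------------------------------------------------------------

def extract_shared_regions(plastomes: Sequence[Plastome]) -> Dict[str, dict]:
    """Gene and spacer sequence sets shared by >= 2 taxa.

    Returns ``{name: {"class": cls, "seqs": {taxon: seq}}}``. Gene sequences
    are strand-normalised; spacers are named 'A-B' for each ordered adjacent
    gene pair and zero-length spacers are skipped.
    """
    per_name: Dict[str, dict] = {}
    for p in plastomes:
        genes = sorted([g for g in p.genes if g.kind != "intergenic"],
                       key=lambda g: (g.start, g.end))
        if not genes:
            raise ConsistencyError(f"{p.id}: plastome has no annotations")
        seen = set()
        for g in genes:
            if g.name in seen:
                continue  # one copy per taxon (IR duplicates, split parts)
            seen.add(g.name)
            rec = per_name.setdefault(g.name, {"class": "coding", "seqs": {}})
            rec["seqs"][p.id] = p.gene_seq(g)
        for g1, g2 in zip(genes, genes[1:]):
            if g2.start <= g1.end:
                continue
            name = f"{g1.name}-{g2.name}"
            rec = per_name.setdefault(name, {"class": "noncoding", "seqs": {}})
            rec["seqs"].setdefault(p.id, p.seq[g1.end:g2.start])
    return {name: rec for name, rec in per_name.items()
            if len(rec["seqs"]) >= 2}


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _nw_pair(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Global Needleman-Wunsch; returns the two gapped strings."""
    la, lb = len(a), len(b)
    score = np.zeros((la + 1, lb + 1), dtype=np.int32)
    score[:, 0] = gap * np.arange(la + 1)
    score[0, :] = gap * np.arange(lb + 1)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    aa = seq_to_array(a)
    bb = seq_to_array(b)
    for i in range(1, la + 1):
        sub = np.where(bb == aa[i - 1], match, mismatch)
        row_prev = score[i - 1]
        row = score[i]
        for j in range(1, lb + 1):
            d = row_prev[j - 1] + sub[j - 1]
            u = row_prev[j] + gap
            l = row[j - 1] + gap
            best = d
            p = 0
            if u > best:
                best, p = u, 1
            if l > best:
                best, p = l, 2
            row[j] = best
            ptr[i, j] = p
    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif p == 1:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _kmer_set(s: str, k: int = 6):
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def align_region(seqs, name: str = "region", cls: str = "noncoding",
                 mode: str = "internal") -> RegionAlignment:
    """Align one region's sequences.

    ``internal`` runs the built-in progressive aligner (match 1 / mismatch -1 /
    gap -2; sequences joined to the most k-mer-similar centre first) and is
    intended for test/toy scale. ``external`` ingests an already-aligned FASTA
    file (e.g. produced by MAFFT).
    """
    if mode == "external":
        recs = list(SeqIO.parse(str(seqs), "fasta"))
        if not recs:
            raise FormatError(f"{seqs}: empty alignment")
        rows = [str(r.seq).upper() for r in recs]
        if len({len(r) for r in rows}) != 1:
            raise FormatError(f"{seqs}: rows differ in length")
        return RegionAlignment(name=name, cls=cls,
                               taxa=[r.id for r in recs], rows=rows)
    if isinstance(seqs, dict):
        taxa = list(seqs)
        seq_list = [seqs[t] for t in taxa]
    else:
        seq_list = list(seqs)
        taxa = [f"seq{i + 1}" for i in range(len(seq_list))]
    if len(seq_list) < 2:
        raise ValueError("need >= 2 sequences")
    # guide order: centre = sequence with highest total k-mer similarity;
    # each remaining sequence is aligned to the growing centre row and the
    # new gaps are threaded through all existing rows ("once a gap, always
    # a gap")
    sets = [_kmer_set(s) for s in seq_list]
    sims = [sum(len(si & sj) for j, sj in enumerate(sets) if j != i)
            for i, si in enumerate(sets)]
    order = sorted(range(len(seq_list)), key=lambda i: -sims[i])
    centre = order[0]
    msa_rows = {centre: seq_list[centre]}
    for idx in order[1:]:
        ref = msa_rows[centre]
        ga, gb = _nw_pair(ref.replace("-", ""), seq_list[idx])
        # columns: 'old' = pre-existing centre gap, 'new' = insertion in the
        # incoming sequence, 'both' = aligned pair
        out_cols = []
        ri = ai = 0
        while ri < len(ref) or ai < len(ga):
            if ri < len(ref) and ref[ri] == "-":
                out_cols.append(("old", "-"))
                ri += 1
            elif ai < len(ga) and ga[ai] == "-":
                out_cols.append(("new", gb[ai]))
                ai += 1
            else:
                out_cols.append(("both", gb[ai]))
                ri += 1
                ai += 1
        new_rows = {}
        for k, row in msa_rows.items():
            it = iter(row)
            new_rows[k] = "".join("-" if kind == "new" else next(it)
                                  for kind, _ in out_cols)
        new_rows[idx] = "".join("-" if kind == "old" else ch
                                for kind, ch in out_cols)
        msa_rows = new_rows
    rows = [msa_rows[i] for i in range(len(seq_list))]
    aln = RegionAlignment(name=name, cls=cls, taxa=taxa, rows=rows)
    for i, s in enumerate(seq_list):
        assert aln.degap(i) == s, "aligner altered sequence content"
    return aln


def write_region_alignment(aln: RegionAlignment, path) -> None:
    with open(path, "w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


# ---------------------------------------------------------------------------
# Pi
# ---------------------------------------------------------------------------

def nucleotide_diversity(alignment: RegionAlignment,
                         deletion: str = "complete") -> DiversityRecord:
    """Nei's pi over retained columns.

    ``complete`` removes every column containing a gap or N before computing;
    ``pairwise`` drops such sites per sequence pair instead.
    """
    arr = np.vstack([seq_to_array(r.replace("-", "N")) for r in alignment.rows])
    n = arr.shape[0]
    valid = arr < 4
    if deletion == "complete":
        keep = valid.all(axis=0)
        sites = int(keep.sum())
        if sites == 0:
            raise NoSitesError(f"{alignment.name}: no columns survive deletion")
        sub = arr[:, keep]
        total = 0.0
        for i, j in combinations(range(n), 2):
            total += np.mean(sub[i] != sub[j])
    elif deletion == "pairwise":
        total = 0.0
        sites = alignment.length
        min_sites = sites
        for i, j in combinations(range(n), 2):
            ok = valid[i] & valid[j]
            if not ok.any():
                raise NoSitesError(f"{alignment.name}: pair with no shared sites")
            min_sites = min(min_sites, int(ok.sum()))
            total += np.mean(arr[i][ok] != arr[j][ok])
        sites = min_sites
    else:
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    pi = total / (n * (n - 1) / 2)
    return DiversityRecord(name=alignment.name, cls=alignment.cls,
                           pi=float(pi), n_taxa=n, n_sites_used=sites)


@dataclass
class DiversitySummary:
    class_means: Dict[str, float]
    table: pd.DataFrame           # ranked descending by pi
    top: pd.DataFrame


def diversity_summary(records: Sequence[DiversityRecord],
                      top_k: int = 10) -> DiversitySummary:
    """Arithmetic mean pi per class plus the ranked region table."""
    if not records:
        raise ValueError("no diversity records")
    df = pd.DataFrame([{"name": r.name, "class": r.cls, "pi": r.pi,
                        "n_taxa": r.n_taxa, "n_sites": r.n_sites_used}
                       for r in records])
    means = df.groupby("class")["pi"].mean().to_dict()
    ranked = df.sort_values(["pi", "name"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    return DiversitySummary(class_means=means, table=ranked,
                            top=ranked.head(top_k))
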