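"""Reading, writing and the canonical in-memory plastome representation.

Internal coordinates are 0-based half-open on the forward strand of one
linearization of the circle; external tables (GFF3-like TSV) are 1-based
inclusive. Features that wrap the origin are split into sub-intervals on load
so all downstream interval code stays linear.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List

from Bio import SeqIO

from ._seq import gc_content, revcomp
from .errors import AlphabetError, ConsistencyError, FormatError

_IUPAC_EXTRA = set("RYSWKMBDHV")
_VALID = set("ACGTN")

GENE_KINDS = ("CDS", "tRNA", "rRNA", "gene", "intergenic")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature on the linearized forward strand.

    ``start``/``end`` are 0-based half-open; ``strand`` is '+' or '-';
    ``kind`` is one of CDS, tRNA, rRNA, gene, intergenic.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval {self.name}: [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self):
        return self.end - self.start


@dataclass
class Plastome:
    """A (usually circular) plastid genome with its gene annotations."""

    id: str
    seq: str
    circular: bool = True
    genes: List[GeneFeature] = field(default_factory=list)
    n_ambiguous: int = 0  # IUPAC codes degraded to N on load

    def __post_init__(self):
        if not self.seq:
            raise FormatError(f"{self.id}: empty sequence")
        for g in self.genes:
            if g.end > len(self.seq):
                raise ValueError(f"{self.id}: feature {g.name} exceeds genome length")

    def __len__(self):
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_content(self.seq)

    def gene_seq(self, feature: GeneFeature) -> str:
        """Feature sequence on its own strand."""
        s = self.seq[feature.start:feature.end]
        return revcomp(s) if feature.strand == "-" else s


def _clean_seq(raw: str, sid: str) -> tuple[str, int]:
    s = raw.upper().replace("U", "T")
    extra = sum(s.count(c) for c in _IUPAC_EXTRA)
    if extra:
        for c in _IUPAC_EXTRA:
            s = s.replace(c, "N")
    bad = set(s) - _VALID
    if bad:
        raise AlphabetError(f"{sid}: non-nucleotide characters {sorted(bad)}")
    return s, extra


def read_fasta(path, circular: bool = True) -> List[Plastome]:
    """Read a (multi-record) nucleotide FASTA into Plastome objects.

    Lowercase is uppercased, U is mapped to T, and IUPAC ambiguity codes other
    than N are degraded to N with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    out = []
    total_amb = 0
    for rec in records:
        s, n_amb = _clean_seq(str(rec.seq), rec.id)
        total_amb += n_amb
        out.append(Plastome(id=rec.id, seq=s, circular=circular, n_ambiguous=n_amb))
    if total_amb:
        warnings.warn(f"{path}: {total_amb} ambiguity base(s) degraded to N")
    return out


def write_fasta(plastomes: Iterable[Plastome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for p in plastomes:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.seq), width):
                fh.write(p.seq[i:i + width] + "\n")


def _split_location(loc, n: int):
    """Yield (start, end) sub-intervals of a Biopython location, splitting
    compound/origin-wrapping parts."""
    for part in getattr(loc, "parts", [loc]):
        s, e = int(part.start), int(part.end)
        if s < e:
            yield s, e


def read_genbank(path) -> Plastome:
    """Read one GenBank flatfile record, populating gene annotations.

    Coordinates are converted to 0-based half-open; join() locations are split
    into sub-intervals; topology is taken from the LOCUS line.
    """
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record") from None
    raw = str(rec.seq)
    if not raw or set(raw) == {"N"}:
        raise FormatError(f"{path}: record has no ORIGIN sequence")
    seq, n_amb = _clean_seq(raw, rec.id)
    circular = rec.annotations.get("topology", "circular") == "circular"
    n = len(seq)

    feats = []
    seen = set()  # (name, start) of specific features, to skip duplicate 'gene' lines
    for ftype in ("CDS", "tRNA", "rRNA"):
        for f in rec.features:
            if f.type != ftype:
                continue
            name = f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
            strand = "-" if f.location.strand == -1 else "+"
            for s, e in _split_location(f.location, n):
                feats.append(GeneFeature(name, s, e, strand, ftype))
                seen.add((name, s))
    for f in rec.features:
        if f.type != "gene":
            continue
        name = f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
        strand = "-" if f.location.strand == -1 else "+"
        parts = list(_split_location(f.location, n))
        if any((name, s) in seen for s, _ in parts):
            continue
        if any(any(s <= g.start < e for g in feats if g.name == name) for s, e in parts):
            continue
        for s, e in parts:
            feats.append(GeneFeature(name, s, e, strand, "gene"))
    feats.sort(key=lambda g: (g.start, g.end))
    return Plastome(id=rec.id, seq=seq, circular=circular, genes=feats, n_ambiguous=n_amb)


def fetch_genbank(accession: str, dest_dir, timeout: float = 30.0):
    """Download a GenBank flatfile for one accession from NCBI efetch.

    Returns the path to the cached file; reuses an existing cache. Requires
    network access.
    """
    import os
    import urllib.request

    os.makedirs(str(dest_dir), exist_ok=True)
    path = os.path.join(str(dest_dir), f"{accession}.gb")
    if os.path.exists(path) and os.path.getsize(path) > 0:
        return path
    url = (
        "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
        f"?db=nucleotide&id={accession}&rettype=gbwithparts&retmode=text"
    )
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    with open(path, "wb") as fh:
        fh.write(data)
    return path


# ---------------------------------------------------------------------------
# GFF3-like annotation tables (9 columns, 1-based inclusive)
# ---------------------------------------------------------------------------

def write_annotation_table(plastome: Plastome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in plastome.genes:
            attrs = f"Name={g.name}"
            fh.write(
                f"{plastome.id}\tplastokit\t{g.kind}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_annotation_table(path) -> List[GeneFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            _, _, kind, start, end, _, strand, _, attrs = cols
            name = "?"
            for kv in attrs.split(";"):
                if kv.startswith("Name="):
                    name = kv[5:]
            feats.append(GeneFeature(name, int(start) - 1, int(end), strand, kind))
    return feats


# ---------------------------------------------------------------------------
# Canonical orientation
# ---------------------------------------------------------------------------

def rotate_to_lsc_origin(plastome: Plastome, partition) -> Plastome:
    """Rotate a circular plastome so the LSC starts at position 0.

    With IRb defined as the IR copy whose clockwise neighbour is the SSC
    (the package-wide convention), the clockwise region order is always
    LSC-IRb-SSC-IRa, so a rotation suffices; gene coordinates are remapped and
    features that would wrap after rotation are split. Length is unchanged.
    """
    n = len(plastome)
    if partition.n != n:
        raise ConsistencyError(
            f"partition is for a genome of length {partition.n}, not {n}"
        )
    k = partition.lsc.start % n
    if k == 0:
        return plastome
    if not plastome.circular:
        raise ConsistencyError(f"{plastome.id}: cannot rotate a linear genome")
    seq = plastome.seq[k:] + plastome.seq[:k]
    genes = []
    for g in plastome.genes:
        s = (g.start - k) % n
        e = s + len(g)
        if e <= n:
            genes.append(replace(g, start=s, end=e))
        else:  # wraps the new origin: split
            genes.append(replace(g, start=s, end=n))
            genes.append(replace(g, start=0, end=e - n))
    genes.sort(key=lambda g: (g.start, g.end))
    return Plastome(
        id=plastome.id, seq=seq, circular=True, genes=genes,
        n_ambiguous=plastome.n_ambiguous,
    )
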