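import pytest

import plastokit as pk


@pytest.fixture(scope="session")
def small_family():
    """One ~30 kb synthetic family (8 taxa) shared across tests."""
    cfg = pk.SynthConfig.small(seed=3)
    anc, fam, truth = pk.make_family(cfg)
    return anc, fam, truth


@pytest.fixture(scope="session")
def family_alignments(small_family):
    """Gap-free per-region alignments (tips are positionally aligned)."""
    _, fam, _ = small_family
    regions = pk.extract_shared_regions(fam)
    alns = {}
    for name, rec in regions.items():
        alns[name] = pk.RegionAlignment(
            name=name, cls=rec["class"], taxa=list(rec["seqs"]),
            rows=list(rec["seqs"].values()))
    return alns


@pytest.fixture(scope="session")
def family_diversity(family_alignments):
    return [pk.nucleotide_diversity(a) for a in family_alignments.values()]


def make_alignment(rows, name="toy", cls="noncoding", taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return pk.RegionAlignment(name=name, cls=cls, taxa=taxa, rows=list(rows))


@pytest.fixture
def toy_alignment():
    return make_alignment
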