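import pytest

from hgcmine import loci as lc
from hgcmine import screen as sc
from hgcmine import synthetic as syn


@pytest.fixture(scope="session")
def figure2_fixture():
    """Deterministic 25-locus catalog: genes, contigs, ground truth."""
    return syn.build_figure2_fixture()


@pytest.fixture(scope="session")
def profiles():
    return {
        t: sc.build_profile(syn.reference_alignment(t), t) for t in ("hgcA", "hgcB")
    }


@pytest.fixture(scope="session")
def fixture_pipeline(figure2_fixture, profiles):
    """Screen -> verify -> call_loci on the deterministic fixture."""
    genes, contigs, truth = figure2_fixture
    hits = sc.screen_candidates(genes, profiles=profiles)
    verified = sc.verify_candidates(hits, genes)
    loci_list = lc.call_loci(verified, genes, contigs)
    return {
        "genes": genes,
        "contigs": contigs,
        "truth": truth,
        "hits": hits,
        "verified": verified,
        "loci": loci_list,
        "summary": lc.summarize_loci(loci_list),
    }


@pytest.fixture(scope="session")
def reference_fixture():
    return syn.build_reference_fixture()
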