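import numpy as np
import pandas as pd
import pytest

from genegap import corpus as corpus_mod


@pytest.fixture()
def toy_registry_df() -> pd.DataFrame:
    """Six genes: five clean (four protein-coding), one undefined symbol."""
    return pd.DataFrame({
        "GeneID": [1, 2, 3, 4, 5, 6],
        "Ensembl": [f"ENSG{i:011d}" for i in range(1, 7)],
        "Symbol": ["A1", "B2", "C3", "D4", "E5", "-"],
        "Synonyms": ["A1x|A1y", "-", "C3x", "-", "-", "-"],
        "type_of_gene": ["protein-coding"] * 4 + ["ncRNA", "protein-coding"],
    })


@pytest.fixture()
def toy_registry(toy_registry_df) -> pd.DataFrame:
    return corpus_mod.load_gene_registry(toy_registry_df)


@pytest.fixture()
def toy_articles() -> pd.DataFrame:
    df = pd.DataFrame({
        "pmid": [101, 102, 103, 104, 105],
        "year": [2000, 2005, 2010, 2015, 2020],
        "is_research_article": [1, 1, 1, 0, 1],
        "citation_count": [5, 50, 10, 3, 0],
        "mesh_terms": ["D1", "D1|D2", "D2", "D1", "D2"],
    })
    return corpus_mod.load_articles(df)


@pytest.fixture()
def toy_mentions() -> pd.DataFrame:
    """Resolved (pmid, gene) pairs consistent with toy_articles/registry."""
    return pd.DataFrame({
        "pmid": [101, 101, 102, 103, 105],
        "entrez_id": [1, 2, 1, 3, 2],
    })


@pytest.fixture(scope="session")
def small_corpus():
    """One lean synthetic corpus shared by read-only tests."""
    from genegap.simulate import SyntheticConfig, generate_corpus
    return generate_corpus(SyntheticConfig(seed=11, n_genes=600,
                                           n_focus_per_assay=2,
                                           hits_per_study=(40, 80),
                                           derivation_sources=False))


def spawn_seeds(master: int, n: int) -> list[int]:
    """Independent per-replicate seeds below 2**31 derived from one master."""
    ss = np.random.SeedSequence(master)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
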