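import numpy as np
import pytest
from hypothesis import settings

from snobpb.synthetic import canonical_specs, generate_dataset, shuffle_labels

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specs():
    return canonical_specs()


@pytest.fixture(scope="session")
def separable_windows(specs):
    """150+150 windows with residue W planted at position 5 of every positive
    and banned there in every negative — perfectly separable by design."""
    return generate_dataset(specs["separable"])


@pytest.fixture(scope="session")
def null_windows(specs):
    """200+200 motif-free windows with labels randomly permuted."""
    w = generate_dataset(specs["null"])
    return shuffle_labels(w, seed=specs["null"].seed)


@pytest.fixture(scope="session")
def weak_motif_windows(specs):
    """2000+2000 windows with K enriched threefold at position 3."""
    return generate_dataset(specs["weak_motif"])


@pytest.fixture(scope="session")
def padded_windows(specs):
    return generate_dataset(specs["padded"])


@pytest.fixture()
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">p1\nMKTACDEFGHIKLMNPQRSTVWYACDC\n"
        ">p2\nCDEFGHIKLMN\n"
        ">p3\nGGGGGGGGGG\n"  # no cysteine
    )
    return path


@pytest.fixture()
def toy_sites(tmp_path):
    path = tmp_path / "toy.sites.tsv"
    path.write_text(
        "protein_id\tposition\tlabel\n"
        "p1\t5\t1\n"
        "p1\t25\t-1\n"
        "p2\t1\tpos\n"
    )
    return path
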