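import pytest

from clasp import default_mito_model, generate_organelle, simulate_crosslinks
from clasp.simulate import organelle_annotations


@pytest.fixture(scope="session")
def mito():
    return default_mito_model()


@pytest.fixture(scope="session")
def small_organelle(mito):
    """60 proteins, mixed soluble/membrane, fixed seed."""
    return generate_organelle(60, lm_fraction=0.3, membrane_fraction=0.4,
                              model=mito, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_organelle):
    links, truth = simulate_crosslinks(small_organelle, 800, noise_rate=0.0, seed=12)
    return small_organelle, links, truth


@pytest.fixture(scope="session")
def small_annotations(small_organelle):
    """Annotation table the simulator would write for the organelle."""
    return organelle_annotations(small_organelle, seed=small_organelle.seed)


@pytest.fixture
def xl_csv(tmp_path):
    """Write a cross-link CSV in the default dialect from row tuples."""

    def write(rows, name="links.csv", header="Protein A,Residue A,Protein B,Residue B"):
        path = tmp_path / name
        path.write_text("\n".join([header] + [",".join(map(str, r)) for r in rows]) + "\n")
        return path

    return write
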