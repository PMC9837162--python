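import numpy as np
import pytest

import tatakd as tk

TOY_MATRIX_TEXT = """\
# width-6 toy count matrix for oracle tests
A 10  1  0  5  2  1
C  2  1  0  1  2  1
G  1  1 12  1  2  1
T  1 11  0  5  6  9
"""


@pytest.fixture(scope="session")
def default_matrix():
    return tk.default_matrix()


@pytest.fixture(scope="session")
def toy_matrix(tmp_path_factory):
    path = tmp_path_factory.mktemp("matrix") / "toy.txt"
    path.write_text(TOY_MATRIX_TEXT)
    return tk.load_matrix(path)


@pytest.fixture(scope="session")
def anchors():
    return tk.CalibrationAnchors()


def random_dna(rng: np.random.Generator, length: int = 90) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_cohort(n: int = 4, family=tk.GeneFamily.GLOBULIN, seed: int = 0):
    """Small hand-assembled cohort of unambiguous 90-mers."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        group = tk.PlantGroup.FOOD if i % 2 == 0 else tk.PlantGroup.NON_FOOD
        records.append(
            tk.PromoterRecord(
                record_id=f"rec{i:02d}",
                species=f"sp{i % 3}",
                gene_family=family,
                group=group,
                sequence=random_dna(rng),
            )
        )
    return tk.Cohort(records=records, provenance="test")
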