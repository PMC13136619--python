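import numpy as np
import pandas as pd
import pytest

from codelnet.genomics_io import ExpressionMatrix, GeneAnnotation
from codelnet import simulation as sim

DELETED = {("chr1", "p"), ("chr4", "q")}
SISTERS = {("chr1", "q"), ("chr4", "p")}


@pytest.fixture(scope="session")
def small_genome() -> GeneAnnotation:
    return sim.simulate_genome(n_chrom=2, genes_per_arm=30, seed=11)


@pytest.fixture(scope="session")
def default_truth():
    ann = sim.simulate_genome(seed=11)
    return sim.simulate_network(ann, seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_truth):
    return sim.simulate_cells(default_truth, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0, 0.0], [4.0, 4.5, 5.0], [0.0, 0.0, 0.0]],
        index=["gA", "gB", "gC"],
        columns=["c1", "c2", "c3"],
    )
    return ExpressionMatrix(data)


def make_annotation(rows) -> GeneAnnotation:
    """rows: iterable of (gene_id, chromosome, arm, start_bp)."""
    return GeneAnnotation(
        pd.DataFrame(
            [
                {"gene_id": g, "chromosome": c, "arm": a,
                 "start_bp": s, "end_bp": s + 10}
                for g, c, a, s in rows
            ]
        )
    )
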