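import numpy as np
import pandas as pd
import pytest

from funcdiff import (
    FeatureMatrix,
    GeneRecord,
    KoAnnotation,
    Pathway,
    PathwayOntology,
)


@pytest.fixture
def small_ontology() -> PathwayOntology:
    return PathwayOntology(
        pathways={
            "p1": Pathway("histidine biosynthesis", frozenset({"K00001", "K00002"})),
            "p2": Pathway("PTS", frozenset({"K00003", "K00004", "K00005", "K00006"})),
            "p3": Pathway("chemotaxis", frozenset({"K00002", "K00007"})),
        }
    )


def annotation_from_kos(unit_id: str, kos) -> KoAnnotation:
    return KoAnnotation(
        unit_id=unit_id,
        records=[GeneRecord(gene_id=f"{unit_id}_g{i}", ko=ko) for i, ko in enumerate(kos)],
    )


def sample_from_cells(sample_id: str, cells) -> KoAnnotation:
    """cells: iterable of (ko, genus, count)."""
    return KoAnnotation(
        unit_id=sample_id,
        records=[
            GeneRecord(gene_id=f"{sample_id}_o{i}", ko=ko, genus=genus, coverage=float(c))
            for i, (ko, genus, c) in enumerate(cells)
        ],
    )


def matrix_from_array(values, row_ids=None, col_ids=None, role="generic", normalization="raw"):
    values = np.asarray(values, dtype=float)
    rows = row_ids or [f"r{i}" for i in range(values.shape[0])]
    cols = col_ids or [f"c{j}" for j in range(values.shape[1])]
    return FeatureMatrix(
        role=role,
        data=pd.DataFrame(values, index=rows, columns=cols),
        normalization=normalization,
    )
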