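"""Feature-matrix builders against brute-force tallies and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcdiff import (
    GeneRecord,
    KoAnnotation,
    MatrixError,
    Pathway,
    PathwayOntology,
    build_genus_abundance,
    build_ko_genus_matrix,
    build_ko_presence,
    build_pathway_genus_matrix,
    build_pathway_matrix,
    complement_adjust,
    filter_rows_by_sd,
    normalize_per_million,
    pathway_coverage,
    shannon_index,
    split_row_label,
)

from conftest import annotation_from_kos, matrix_from_array, sample_from_cells

KOS = [f"K{i:05d}" for i in range(1, 21)]
GENERA = ["Lactobacillus", "Oenococcus", "Pantoea"]


# ---------------------------------------------------------------------------
# randomized brute-force oracle
# ---------------------------------------------------------------------------


def random_instance(seed, n_units=4, n_kos=12, n_pathways=4):
    """Random small instance: KO sets per organism, coverage cells per
    sample, and an ontology — together with plain-python reference tallies."""
    rng = np.random.default_rng(seed)
    kos = KOS[:n_kos]
    orgs = {
        f"org{u}": {k for k in kos if rng.random() < 0.5} | {kos[u % n_kos]}
        for u in range(n_units)
    }
    samples = {}
    for u in range(n_units):
        cells = []
        for ko in kos:
            for genus in GENERA:
                if rng.random() < 0.4:
                    cells.append((ko, genus, int(rng.integers(1, 50))))
        # every sample needs at least one read
        if not cells:
            cells.append((kos[0], GENERA[0], 1))
        samples[f"s{u}"] = cells
    pathways = {}
    for p in range(n_pathways):
        members = {k for k in kos if rng.random() < 0.4} or {kos[p]}
        pathways[f"p{p}"] = Pathway(f"pw{p}", frozenset(members))
    return orgs, samples, PathwayOntology(pathways=pathways)


@pytest.mark.parametrize("seed", range(8))
def test_builders_match_nested_loop_tallies(seed):
    orgs, samples, ont = random_instance(seed)
    org_anns = [annotation_from_kos(u, sorted(ks)) for u, ks in orgs.items()]
    sample_anns = [sample_from_cells(s, cells) for s, cells in samples.items()]

    k = build_ko_presence(org_anns)
    for ko in k.row_ids:
        for unit in k.col_ids:
            assert k.data.loc[ko, unit] == (1.0 if ko in orgs[unit] else 0.0)

    p = build_pathway_matrix(org_anns, ont)
    for pid in p.row_ids:
        members = ont.members(pid)
        for unit in p.col_ids:
            expected = len(orgs[unit] & members) / len(members)
            assert p.data.loc[pid, unit] == pytest.approx(expected)

    g = build_genus_abundance(sample_anns)
    for genus in g.row_ids:
        for s in g.col_ids:
            expected = sum(c for ko, ge, c in samples[s] if ge == genus)
            assert g.data.loc[genus, s] == expected

    a = build_ko_genus_matrix(sample_anns)
    for rid in a.row_ids:
        ko, genus = split_row_label(rid)
        for s in a.col_ids:
            expected = sum(c for k_, ge, c in samples[s] if k_ == ko and ge == genus)
            assert a.data.loc[rid, s] == expected

    pm = build_pathway_genus_matrix(sample_anns, ont)
    for rid in pm.row_ids:
        pid, genus = split_row_label(rid)
        members = ont.members(pid)
        for s in pm.col_ids:
            distinct = {k_ for k_, ge, _ in samples[s] if ge == genus}
            expected = len(distinct & members) / len(members)
            assert pm.data.loc[rid, s] == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(4))
def test_genus_summed_a_matrix_reproduces_g_exactly(seed):
    _, samples, _ = random_instance(seed)
    anns = [sample_from_cells(s, cells) for s, cells in samples.items()]
    g = build_genus_abundance(anns)
    a = build_ko_genus_matrix(anns)
    genera = [split_row_label(r)[1] for r in a.row_ids]
    summed = a.data.groupby(genera).sum()
    assert (summed.loc[g.row_ids] == g.data).all().all()


def test_builders_invariant_under_record_order(small_ontology):
    cells = [("K00001", "Lactobacillus", 2), ("K00003", "Pantoea", 7),
             ("K00001", "Lactobacillus", 3)]
    a = sample_from_cells("s1", cells)
    b = sample_from_cells("s2", cells)
    fwd = build_genus_abundance([a, b])
    rev = build_genus_abundance(
        [
            KoAnnotation(unit_id=x.unit_id, records=list(reversed(x.records)))
            for x in (a, b)
        ]
    )
    assert (fwd.data == rev.data).all().all()


# ---------------------------------------------------------------------------
# individual builders
# ---------------------------------------------------------------------------


class TestKoPresence:
    def test_union_of_kos(self):
        m = build_ko_presence(
            [annotation_from_kos("org1", ["K00001"]),
             annotation_from_kos("org2", ["K00001", "K00002"])]
        )
        assert m.data.loc["K00001"].tolist() == [1.0, 1.0]
        assert m.data.loc["K00002"].tolist() == [0.0, 1.0]

    def test_duplicate_ko_still_presence(self):
        ann = KoAnnotation(
            unit_id="org",
            records=[GeneRecord("g1", "K00001"), GeneRecord("g2", "K00001")],
        )
        m = build_ko_presence([ann, annotation_from_kos("o2", ["K00002"])])
        assert m.data.loc["K00001", "org"] == 1.0

    def test_unit_without_annotated_genes_is_error(self):
        empty = KoAnnotation(unit_id="void", records=[GeneRecord("g1", None)])
        with pytest.raises(MatrixError, match="void"):
            build_ko_presence([empty])


class TestPathwayCoverage:
    def test_ratio_bounds(self, small_ontology):
        cov = pathway_coverage({"K00003", "K00004"}, small_ontology)
        assert cov["p2"] == 0.5  # 2 of 4 PTS members
        assert cov["p1"] == 0.0
        cov_full = pathway_coverage({"K00001", "K00002"}, small_ontology)
        assert cov_full["p1"] == 1.0

    def test_monotone_under_ko_growth(self, small_ontology):
        small = pathway_coverage({"K00001"}, small_ontology)
        bigger = pathway_coverage({"K00001", "K00002", "K00007"}, small_ontology)
        assert (bigger >= small).all()
        assert ((bigger >= 0) & (bigger <= 1)).all()

    def test_unit_with_no_pathway_kos_gives_zero_column(self, small_ontology):
        m = build_pathway_matrix(
            [annotation_from_kos("org", ["K09999"]),
             annotation_from_kos("org2", ["K00001"])],
            small_ontology,
        )
        assert (m.data["org"] == 0).all()


class TestNormalization:
    def test_per_million_forced_by_formula(self):
        m = matrix_from_array([[2.0], [3.0], [5.0]], role="G")
        norm = normalize_per_million(m)
        assert norm.data.iloc[:, 0].tolist() == [200000.0, 300000.0, 500000.0]

    def test_idempotent_on_normalized_input(self):
        m = matrix_from_array([[250000.0], [750000.0]], role="G")
        norm = normalize_per_million(normalize_per_million(m))
        assert norm.data.iloc[:, 0].tolist() == [250000.0, 750000.0]

    def test_zero_column_is_error(self):
        m = matrix_from_array([[0.0], [0.0]], role="G")
        with pytest.raises(MatrixError, match="zero-sum"):
            normalize_per_million(m)

    def test_complement_adjust_restores_column_sums(self):
        m = matrix_from_array(
            [[200000.0], [300000.0], [500000.0]],
            row_ids=["Lactobacillus", "Oenococcus", "Pantoea"],
            role="G",
            normalization="per_million",
        )
        adj = complement_adjust(m, "Lactobacillus")
        assert "Lactobacillus" not in adj.row_ids
        assert adj.data.sum(axis=0).iloc[0] == pytest.approx(1e6)
        # non-focal entries scaled by 1/(1 - 0.2)
        assert adj.data.loc["Oenococcus"].iloc[0] == pytest.approx(300000 / 0.8)

    def test_complement_adjust_zero_focal_leaves_column(self):
        m = matrix_from_array(
            [[0.0], [1000000.0]],
            row_ids=["Lactobacillus", "Oenococcus"],
            role="G",
            normalization="per_million",
        )
        adj = complement_adjust(m, "Lactobacillus")
        assert adj.data.loc["Oenococcus"].iloc[0] == 1000000.0

    def test_complement_adjust_saturated_focal_is_error(self):
        m = matrix_from_array(
            [[1000000.0], [0.0]],
            row_ids=["Lactobacillus", "Oenococcus"],
            role="G",
            normalization="per_million",
        )
        with pytest.raises(MatrixError, match="fraction is 1"):
            complement_adjust(m, "Lactobacillus")

    def test_complement_adjust_missing_focal_is_error(self):
        m = matrix_from_array(
            [[1e6]], row_ids=["Oenococcus"], role="G", normalization="per_million"
        )
        with pytest.raises(MatrixError, match="not present"):
            complement_adjust(m, "Saccharomyces")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 1000, size=(5, 4)).astype(float) + 1.0
        genera = ["Lactobacillus", "Oenococcus", "Pantoea", "Vitis", "Dyella"]
        m = matrix_from_array(vals, row_ids=genera, role="G")
        norm = normalize_per_million(m)
        assert np.allclose(norm.values.sum(axis=0), 1e6, rtol=1e-6)
        adj = complement_adjust(norm, "Lactobacillus")
        assert np.allclose(adj.values.sum(axis=0), 1e6, rtol=1e-6)


class TestSdFilter:
    def test_constant_row_dropped_for_positive_threshold(self):
        m = matrix_from_array([[5.0, 5.0], [0.0, 10.0]], row_ids=["const", "varies"])
        kept = filter_rows_by_sd(m, sd_threshold=0.1)
        assert kept.row_ids == ["varies"]

    def test_top_1_keeps_max_sd_row(self):
        m = matrix_from_array(
            [[0.0, 1e6], [400000.0, 600000.0]], row_ids=["wide", "narrow"]
        )
        assert filter_rows_by_sd(m, top_n=1).row_ids == ["wide"]

    def test_top_n_equal_row_count_is_identity(self):
        m = matrix_from_array([[1.0, 2.0], [3.0, 1.0], [0.0, 0.0]])
        kept = filter_rows_by_sd(m, top_n=3)
        assert sorted(kept.row_ids) == sorted(m.row_ids)

    def test_top_n_beyond_row_count_warns_and_returns_all(self):
        m = matrix_from_array([[1.0, 2.0], [3.0, 1.0]])
        with pytest.warns(UserWarning, match="top_n"):
            kept = filter_rows_by_sd(m, top_n=10)
        assert len(kept.row_ids) == 2

    def test_uses_sample_sd_denominator(self):
        m = matrix_from_array([[0.0, 1.0]], row_ids=["r"])
        kept = filter_rows_by_sd(m, sd_threshold=0.7)  # sample SD = 0.7071
        assert kept.row_ids == ["r"]


class TestShannon:
    def test_uniform_closed_form(self):
        assert shannon_index([1, 1, 1, 1]) == pytest.approx(math.log(4))

    def test_single_genus_zero(self):
        assert shannon_index([0, 7, 0]) == 0.0

    def test_two_equal(self):
        assert shannon_index([1, 1]) == pytest.approx(math.log(2))

    def test_all_zero_is_error(self):
        with pytest.raises(MatrixError):
            shannon_index([0.0, 0.0])
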