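"""Construction and normalization of the five feature matrices.

The pipeline compares organisms and metagenome samples through five
labeled matrices, all features-by-units:

* ``K``  — binary KO presence/absence per organism;
* ``P``  — pathway coverage per organism: the number of a pathway's member
  KOs present in the organism divided by the pathway size, in [0, 1];
* ``G``  — read counts summed per genus per sample, optionally normalized
  to reads-per-million and complement-adjusted for an inoculated genus;
* ``A``  — read counts per (KO, genus) combination per sample;
* ``PM`` — pathway coverage per (pathway, genus) combination per sample.

Composite row labels for ``A`` and ``PM`` are ``"<KO>|<genus>"`` and
``"<pathway>|<genus>"``; `split_row_label` recovers the pair. Rows and
columns are ordered lexicographically so outputs are bit-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import KoAnnotation, PathwayOntology

__all__ = [
    "FeatureMatrix",
    "MatrixError",
    "ROW_LABEL_SEP",
    "split_row_label",
    "build_ko_presence",
    "pathway_coverage",
    "build_pathway_matrix",
    "build_genus_abundance",
    "normalize_per_million",
    "complement_adjust",
    "build_ko_genus_matrix",
    "build_pathway_genus_matrix",
    "filter_rows_by_sd",
    "shannon_index",
]

PER_MILLION = 1_000_000.0

#: Separator inside composite row labels of the A and PM matrices.
ROW_LABEL_SEP = "|"


class MatrixError(ValueError):
    """Raised on invalid matrix construction or normalization input."""


def split_row_label(label: str) -> tuple[str, str]:
    """Split an ``A``/``PM`` row label into its (KO-or-pathway, genus) pair."""
    first, _, second = label.partition(ROW_LABEL_SEP)
    return first, second


@dataclass
class FeatureMatrix:
    """A labeled non-negative matrix: rows are features, columns are units.

    ``role`` is one of ``K``, ``P``, ``G``, ``A``, ``PM`` or ``generic``;
    ``normalization`` one of ``raw``, ``per_pathway``, ``per_million``,
    ``complement_adjusted``.
    """

    role: str
    data: pd.DataFrame
    normalization: str = "raw"

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, unit: str) -> np.ndarray:
        return self.data[unit].to_numpy()

    def row_genera(self) -> list[str]:
        """Genus component of every row label (roles G, A, PM)."""
        if self.role == "G":
            return self.row_ids
        return [split_row_label(r)[1] for r in self.row_ids]


def _sorted_frame(cells: dict[tuple[str, str], float], col_order: Sequence[str]) -> pd.DataFrame:
    rows = sorted({r for r, _ in cells})
    df = pd.DataFrame(0.0, index=rows, columns=list(col_order))
    for (r, c), v in cells.items():
        df.loc[r, c] = v
    return df


def build_ko_presence(anns: Sequence[KoAnnotation]) -> FeatureMatrix:
    """Binary KO-presence matrix over the union of observed KOs.

    Entry (j, i) is 1 when KO j occurs in organism i, else 0. A unit with
    no annotated genes carries no information and is an error.
    """
    if not anns:
        raise MatrixError("no annotations given")
    for ann in anns:
        if not ann.kos:
            raise MatrixError(f"unit {ann.unit_id!r} has zero annotated genes")
    cols = sorted(a.unit_id for a in anns)
    by_unit = {a.unit_id: a.kos for a in anns}
    rows = sorted(set().union(*by_unit.values()))
    values = np.zeros((len(rows), len(cols)))
    row_ix = {k: i for i, k in enumerate(rows)}
    for j, unit in enumerate(cols):
        for ko in by_unit[unit]:
            values[row_ix[ko], j] = 1.0
    return FeatureMatrix(
        role="K", data=pd.DataFrame(values, index=rows, columns=cols)
    )


def pathway_coverage(
    ann_or_koset: KoAnnotation | Iterable[str], ont: PathwayOntology
) -> pd.Series:
    """Coverage of every pathway by a unit's KO repertoire.

    For pathway i the coverage is |KOs(unit) ∩ members(i)| / |members(i)|,
    bounded in [0, 1] and monotone under growth of the KO set.
    """
    if len(ont) == 0:
        raise MatrixError("empty pathway ontology")
    kos = ann_or_koset.kos if isinstance(ann_or_koset, KoAnnotation) else set(ann_or_koset)
    vals = {
        pid: len(kos & ont.members(pid)) / len(ont.members(pid))
        for pid in ont.pathway_ids
    }
    return pd.Series(vals, name="coverage").sort_index()


def build_pathway_matrix(
    anns: Sequence[KoAnnotation], ont: PathwayOntology
) -> FeatureMatrix:
    """Stack per-unit pathway coverage vectors into the P matrix."""
    if not anns:
        raise MatrixError("no annotations given")
    cols = sorted(a.unit_id for a in anns)
    by_unit = {a.unit_id: a for a in anns}
    df = pd.DataFrame(
        {unit: pathway_coverage(by_unit[unit], ont) for unit in cols}
    )
    return FeatureMatrix(role="P", data=df, normalization="per_pathway")


def _check_sample_records(anns: Sequence[KoAnnotation]) -> None:
    if not anns:
        raise MatrixError("no sample annotations given")
    for ann in anns:
        for rec in ann.records:
            if rec.coverage is None:
                raise MatrixError(
                    f"record {rec.gene_id!r} in sample {ann.unit_id!r} "
                    "lacks read coverage"
                )


def build_genus_abundance(
    anns: Sequence[KoAnnotation], include_unannotated: bool = False
) -> FeatureMatrix:
    """Sum KO read coverage per genus per sample (raw G matrix).

    By default only KO-annotated ORFs contribute, matching the KO-indexed
    matrices; ``include_unannotated=True`` also counts ORFs without a KO.
    """
    _check_sample_records(anns)
    cols = sorted(a.unit_id for a in anns)
    cells: dict[tuple[str, str], float] = {}
    for ann in anns:
        for rec in ann.records:
            if rec.ko is None and not include_unannotated:
                continue
            genus = rec.genus or "unclassified"
            key = (genus, ann.unit_id)
            cells[key] = cells.get(key, 0.0) + float(rec.coverage)
    df = _sorted_frame(cells, cols)
    for unit in cols:
        if df[unit].sum() <= 0:
            raise MatrixError(f"sample {unit!r} has zero total reads")
    return FeatureMatrix(role="G", data=df)


def normalize_per_million(m: FeatureMatrix) -> FeatureMatrix:
    """Rescale each column to reads-per-million: g_ij / g_j * 1e6."""
    if m.normalization not in ("raw", "per_million"):
        raise MatrixError(f"cannot per-million normalize a {m.normalization} matrix")
    sums = m.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise MatrixError(f"zero-sum column(s): {', '.join(map(str, zero.index))}")
    return FeatureMatrix(
        role=m.role, data=m.data / sums * PER_MILLION, normalization="per_million"
    )


def complement_adjust(m: FeatureMatrix, focal_genus: str) -> FeatureMatrix:
    """Normalize out an inoculated genus: divide by (1 - focal fraction).

    The focal genus row(s) are removed and every remaining entry of
    column j is divided by (1 - f_j), where f_j is the focal genus'
    relative abundance in that column, so column sums return to one
    million. A column consisting entirely of the focal genus has no
    complement and is an error.
    """
    if m.normalization != "per_million":
        raise MatrixError("complement adjustment expects a per_million matrix")
    genera = np.array(m.row_genera())
    focal_mask = genera == focal_genus
    if not focal_mask.any():
        raise MatrixError(f"focal genus {focal_genus!r} not present in matrix rows")
    focal_frac = m.data.loc[focal_mask].sum(axis=0) / PER_MILLION
    saturated = focal_frac[focal_frac >= 1 - 1e-12]
    if len(saturated):
        raise MatrixError(
            "focal genus fraction is 1 in column(s): "
            + ", ".join(map(str, saturated.index))
        )
    rest = m.data.loc[~focal_mask]
    return FeatureMatrix(
        role=m.role,
        data=rest / (1.0 - focal_frac),
        normalization="complement_adjusted",
    )


def build_ko_genus_matrix(anns: Sequence[KoAnnotation]) -> FeatureMatrix:
    """Read counts per (KO, genus) pair per sample (raw A matrix).

    Rows are the (KO, genus) combinations observed in at least one sample,
    labeled ``"KO|genus"``. Summing rows per genus reproduces the G matrix
    restricted to KO-annotated reads exactly.
    """
    _check_sample_records(anns)
    cols = sorted(a.unit_id for a in anns)
    cells: dict[tuple[str, str], float] = {}
    for ann in anns:
        for rec in ann.records:
            if rec.ko is None:
                continue
            genus = rec.genus or "unclassified"
            key = (f"{rec.ko}{ROW_LABEL_SEP}{genus}", ann.unit_id)
            cells[key] = cells.get(key, 0.0) + float(rec.coverage)
    if not cells:
        raise MatrixError("no KO-annotated reads in any sample")
    return FeatureMatrix(role="A", data=_sorted_frame(cells, cols))


def build_pathway_genus_matrix(
    anns: Sequence[KoAnnotation], ont: PathwayOntology
) -> FeatureMatrix:
    """Pathway coverage per (pathway, genus) pair per sample (PM matrix).

    Entry for (pathway p | genus t, sample j) is the number of distinct
    KOs of genus t observed in sample j that are members of p, divided by
    |members(p)| — an ortholog count, not read-weighted.
    """
    _check_sample_records(anns)
    if len(ont) == 0:
        raise MatrixError("empty pathway ontology")
    cols = sorted(a.unit_id for a in anns)
    # distinct KOs per (genus, sample)
    kos_by_genus_sample: dict[tuple[str, str], set[str]] = {}
    genera: set[str] = set()
    for ann in anns:
        for rec in ann.records:
            if rec.ko is None:
                continue
            genus = rec.genus or "unclassified"
            genera.add(genus)
            kos_by_genus_sample.setdefault((genus, ann.unit_id), set()).add(rec.ko)
    cells: dict[tuple[str, str], float] = {}
    for (genus, unit), kos in kos_by_genus_sample.items():
        for pid in ont.pathway_ids:
            members = ont.members(pid)
            hit = len(kos & members)
            if hit:
                label = f"{pid}{ROW_LABEL_SEP}{genus}"
                cells[(label, unit)] = hit / len(members)
    if not cells:
        raise MatrixError("no pathway-genus combinations observed")
    return FeatureMatrix(
        role="PM", data=_sorted_frame(cells, cols), normalization="per_pathway"
    )


def filter_rows_by_sd(
    m: FeatureMatrix,
    top_n: Optional[int] = None,
    sd_threshold: Optional[float] = None,
) -> FeatureMatrix:
    """Keep the rows with the highest across-column standard deviation.

    Exactly one of ``top_n`` / ``sd_threshold`` must be given. SDs use the
    sample (n-1) denominator; ties break lexicographically by row id. A
    ``top_n`` beyond the row count returns all rows with a warning.
    """
    if (top_n is None) == (sd_threshold is None):
        raise MatrixError("give exactly one of top_n or sd_threshold")
    if m.shape[1] < 2:
        raise MatrixError("SD filtering needs at least 2 columns")
    sd = m.data.std(axis=1, ddof=1)
    order = sorted(m.row_ids, key=lambda r: (-sd[r], r))
    if top_n is not None:
        if top_n > len(order):
            warnings.warn(
                f"top_n={top_n} exceeds row count {len(order)}; returning all rows",
                stacklevel=2,
            )
            top_n = len(order)
        keep = order[:top_n]
    else:
        keep = [r for r in order if sd[r] > sd_threshold]
    return FeatureMatrix(
        role=m.role, data=m.data.loc[keep], normalization=m.normalization
    )


def shannon_index(column: np.ndarray | Sequence[float]) -> float:
    """Shannon diversity H = -sum q_i ln q_i (nats) of an abundance vector."""
    q = np.asarray(column, dtype=float)
    if (q < 0).any():
        raise MatrixError("abundances must be non-negative")
    total = q.sum()
    if total <= 0:
        raise MatrixError("all-zero abundance vector")
    q = q[q > 0] / total
    return float(0.0 - (q * np.log(q)).sum())
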