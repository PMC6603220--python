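"""Readers and writers for the tab-separated formats the pipeline consumes.

Three input dialects are supported, all UTF-8, tab-delimited, with
``#``-prefixed comment lines ignored:

* two-column KO annotation tables (``gene_id<TAB>KO``, blank KO for
  unannotated genes), the output dialect of KOALA-style annotators;
* pathway membership tables (``pathway_id<TAB>name<TAB>KO,KO,...``);
* four-column per-ORF read-coverage tables with a genus label
  (``orf_id<TAB>KO<TAB>genus<TAB>read_count``).

Plus a generic labeled-matrix TSV used for every feature matrix the
pipeline emits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "KoAnnotation",
    "Pathway",
    "PathwayOntology",
    "AnnotationError",
    "UNCLASSIFIED_GENUS",
    "read_ko_annotation",
    "write_ko_annotation",
    "read_pathway_table",
    "write_pathway_table",
    "read_genus_coverage_table",
    "write_genus_coverage_table",
    "annotation_fraction",
    "read_matrix",
    "write_matrix",
]

#: KO identifiers are the letter K followed by exactly five digits.
KO_PATTERN = re.compile(r"^K\d{5}$")

#: Reserved genus assigned to ORFs without a taxonomic label, so that
#: per-sample read totals are conserved under normalization.
UNCLASSIFIED_GENUS = "unclassified"


class AnnotationError(ValueError):
    """Raised on malformed annotation/ontology input or invariant violation."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene/ORF of a unit: its KO assignment (if any), genus and coverage."""

    gene_id: str
    ko: Optional[str] = None
    genus: Optional[str] = None
    coverage: Optional[float] = None


@dataclass
class KoAnnotation:
    """Per-unit (organism or metagenome sample) gene-to-KO mapping.

    Invariants enforced at construction: gene ids unique within the unit,
    KO tokens match ``K#####``, coverage non-negative when present.
    """

    unit_id: str
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise AnnotationError(
                    f"duplicate gene_id {rec.gene_id!r} in unit {self.unit_id!r}"
                )
            seen.add(rec.gene_id)
            if rec.ko is not None and not KO_PATTERN.match(rec.ko):
                raise AnnotationError(
                    f"malformed KO {rec.ko!r} for gene {rec.gene_id!r} "
                    f"in unit {self.unit_id!r}"
                )
            if rec.coverage is not None and rec.coverage < 0:
                raise AnnotationError(
                    f"negative coverage for gene {rec.gene_id!r} "
                    f"in unit {self.unit_id!r}"
                )

    @property
    def kos(self) -> set[str]:
        """Set of distinct KOs present in this unit."""
        return {r.ko for r in self.records if r.ko is not None}

    @property
    def n_annotated(self) -> int:
        return sum(1 for r in self.records if r.ko is not None)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Pathway:
    name: str
    members: frozenset[str]


@dataclass
class PathwayOntology:
    """Pathway id -> (name, member KO set); the coverage universe.

    A KO may belong to several pathways; every member set is non-empty
    (it is a coverage denominator).
    """

    pathways: dict[str, Pathway]

    def __post_init__(self) -> None:
        for pid, pw in self.pathways.items():
            if not pw.members:
                raise AnnotationError(f"pathway {pid!r} has an empty KO member set")
            for ko in pw.members:
                if not KO_PATTERN.match(ko):
                    raise AnnotationError(f"malformed KO {ko!r} in pathway {pid!r}")

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.pathways)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id].members

    @property
    def all_kos(self) -> set[str]:
        out: set[str] = set()
        for pw in self.pathways.values():
            out |= pw.members
        return out

    def __len__(self) -> int:
        return len(self.pathways)


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, line) skipping comments and blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_ko_annotation(path: str | Path, unit_id: str) -> KoAnnotation:
    """Parse a two-column ``gene_id<TAB>KO`` table (KOALA output dialect).

    Genes with an empty KO column are retained with ``ko=None`` so the
    annotation fraction can be reported. Malformed KO tokens and duplicate
    gene ids are errors.
    """
    records: list[GeneRecord] = []
    for lineno, line in _data_lines(Path(path)):
        parts = line.split("\t")
        if len(parts) == 1:
            parts = [parts[0], ""]
        if len(parts) != 2:
            raise AnnotationError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        gene_id, ko_tok = parts[0].strip(), parts[1].strip()
        if not gene_id:
            raise AnnotationError(f"{path}:{lineno}: empty gene id")
        if ko_tok and not KO_PATTERN.match(ko_tok):
            raise AnnotationError(f"{path}:{lineno}: malformed KO token {ko_tok!r}")
        records.append(GeneRecord(gene_id=gene_id, ko=ko_tok or None))
    try:
        return KoAnnotation(unit_id=unit_id, records=records)
    except AnnotationError as exc:
        raise AnnotationError(f"{path}: {exc}") from None


def write_ko_annotation(ann: KoAnnotation, path: str | Path) -> None:
    """Write the two-column dialect `read_ko_annotation` parses."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in ann.records:
            fh.write(f"{rec.gene_id}\t{rec.ko or ''}\n")


def read_pathway_table(path: str | Path) -> PathwayOntology:
    """Parse ``pathway_id<TAB>name<TAB>KO,KO,...``.

    Repeated lines for the same pathway contribute the union of their
    members; a pathway that ends up with no members is an error.
    """
    names: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for lineno, line in _data_lines(Path(path)):
        parts = line.split("\t")
        if len(parts) != 3:
            raise AnnotationError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        pid, name, ko_csv = (p.strip() for p in parts)
        kos = {tok.strip() for tok in ko_csv.split(",") if tok.strip()}
        if not kos:
            raise AnnotationError(f"{path}:{lineno}: pathway {pid!r} has no member KOs")
        for ko in kos:
            if not KO_PATTERN.match(ko):
                raise AnnotationError(f"{path}:{lineno}: malformed KO token {ko!r}")
        names.setdefault(pid, name)
        members.setdefault(pid, set()).update(kos)
    return PathwayOntology(
        pathways={
            pid: Pathway(name=names[pid], members=frozenset(members[pid]))
            for pid in members
        }
    )


def write_pathway_table(ont: PathwayOntology, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in ont.pathway_ids:
            pw = ont.pathways[pid]
            fh.write(f"{pid}\t{pw.name}\t{','.join(sorted(pw.members))}\n")


def read_genus_coverage_table(path: str | Path, sample_id: str) -> KoAnnotation:
    """Parse ``orf_id<TAB>KO<TAB>genus<TAB>read_count`` per-sample tables.

    A missing genus label maps to the reserved genus ``unclassified`` so
    read totals are conserved; an empty KO column keeps the ORF with
    ``ko=None``. Negative read counts are errors.
    """
    records: list[GeneRecord] = []
    for lineno, line in _data_lines(Path(path)):
        parts = line.split("\t")
        if len(parts) != 4:
            raise AnnotationError(
                f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
            )
        orf_id, ko_tok, genus, count_tok = (p.strip() for p in parts)
        if not orf_id:
            raise AnnotationError(f"{path}:{lineno}: empty ORF id")
        if ko_tok and not KO_PATTERN.match(ko_tok):
            raise AnnotationError(f"{path}:{lineno}: malformed KO token {ko_tok!r}")
        try:
            count = float(count_tok)
        except ValueError:
            raise AnnotationError(
                f"{path}:{lineno}: unparseable read count {count_tok!r}"
            ) from None
        if count < 0:
            raise AnnotationError(f"{path}:{lineno}: negative read count {count_tok!r}")
        records.append(
            GeneRecord(
                gene_id=orf_id,
                ko=ko_tok or None,
                genus=genus or UNCLASSIFIED_GENUS,
                coverage=count,
            )
        )
    try:
        return KoAnnotation(unit_id=sample_id, records=records)
    except AnnotationError as exc:
        raise AnnotationError(f"{path}: {exc}") from None


def write_genus_coverage_table(ann: KoAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in ann.records:
            cov = rec.coverage if rec.coverage is not None else 0
            cov_tok = f"{int(cov)}" if float(cov).is_integer() else f"{cov!r}"
            fh.write(f"{rec.gene_id}\t{rec.ko or ''}\t{rec.genus or ''}\t{cov_tok}\n")


def annotation_fraction(ann: KoAnnotation) -> float:
    """Fraction of genes/ORFs carrying a KO assignment, in [0, 1]."""
    if not ann.records:
        raise AnnotationError(f"unit {ann.unit_id!r} has no records")
    return ann.n_annotated / len(ann.records)


# ---------------------------------------------------------------------------
# Generic labeled-matrix TSV (used by feature_matrices via write_matrix)
# ---------------------------------------------------------------------------


def write_matrix(m, path: str | Path) -> None:
    """Serialize a FeatureMatrix as a labeled TSV.

    Layout: a ``# role:`` / ``# normalization:`` metadata header, then a
    header row of unit ids and one row per feature. Labels must not
    contain tabs (they would corrupt the format). Round-trips losslessly
    through `read_matrix`.
    """
    for label in list(m.row_ids) + list(m.col_ids):
        if "\t" in label:
            raise AnnotationError(f"label {label!r} contains a tab character")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# role: {m.role}\n")
        fh.write(f"# normalization: {m.normalization}\n")
        fh.write("feature\t" + "\t".join(m.col_ids) + "\n")
        for i, rid in enumerate(m.row_ids):
            vals = "\t".join(repr(float(v)) for v in m.values[i])
            fh.write(f"{rid}\t{vals}\n")


def read_matrix(path: str | Path):
    """Read a labeled TSV written by `write_matrix` back into a FeatureMatrix."""
    from .feature_matrices import FeatureMatrix  # local import: avoid cycle

    path = Path(path)
    role, normalization = "generic", "raw"
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            meta = line.lstrip("#").strip()
            if meta.startswith("role:"):
                role = meta.split(":", 1)[1].strip()
            elif meta.startswith("normalization:"):
                normalization = meta.split(":", 1)[1].strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise AnnotationError(f"{path}: empty matrix file")
    header = body[0].split("\t")
    col_ids = header[1:]
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for line in body[1:]:
        parts = line.split("\t")
        row_ids.append(parts[0])
        rows.append([float(tok) for tok in parts[1:]])
    values = np.array(rows, dtype=float).reshape(len(row_ids), len(col_ids))
    return FeatureMatrix(
        role=role,
        data=pd.DataFrame(values, index=row_ids, columns=col_ids),
        normalization=normalization,
    )
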