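"""Synthetic microbial communities with the structure the pipeline assumes.

Two branches of data are emulated so that every pipeline stage can be
exercised end to end without external sequencing data:

* *isolate genomes*: binary KO repertoires structured by a pathway
  ontology, with planted pathway absences (auxotrophy candidates), a
  configurable rate of background KOs outside the ontology, and a
  configurable fraction of unannotated genes (about half of coding
  sequences typically map to no KO);
* *metagenome time series*: per-sample read counts over (genus, KO)
  cells drawn multinomially from planted genus relative-abundance
  dynamics, with an optional inoculated genus boosted in designated
  samples and class structure (e.g. treated vs. control fermentations)
  expressed through class-dependent dynamics. A Dirichlet-multinomial
  overdispersion option is available since real metagenomes are more
  variable than a plain multinomial.

All generators are deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .annotation_io import GeneRecord, KoAnnotation, Pathway, PathwayOntology

__all__ = [
    "OrganismSpec",
    "SampleSpec",
    "Inoculation",
    "CommunitySpec",
    "SpecError",
    "make_ontology",
    "make_isolates",
    "make_metagenome_series",
    "default_isolate_spec",
    "default_metagenome_spec",
]


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class OrganismSpec:
    """One planted organism: genus, absent pathways, background-KO rate."""

    name: str
    genus: str
    pathway_absences: frozenset[str] = frozenset()
    extra_ko_rate: float = 0.0


@dataclass(frozen=True)
class SampleSpec:
    """One metagenome sample: its class label and timepoint index."""

    name: str
    class_label: str
    timepoint: int
    variety: Optional[str] = None


@dataclass(frozen=True)
class Inoculation:
    """A genus inoculated into specific samples with an abundance boost."""

    genus: str
    samples: tuple[str, ...]
    boost: float


#: Per-genus relative-abundance trajectory: either one list indexed by
#: timepoint (shared across classes) or a map class_label -> list.
Dynamics = Union[Sequence[float], dict]


@dataclass
class CommunitySpec:
    """Complete description of a synthetic community experiment."""

    n_pathways: int = 20
    kos_per_pathway: tuple[int, int] = (5, 15)
    organisms: list[OrganismSpec] = field(default_factory=list)
    samples: list[SampleSpec] = field(default_factory=list)
    genus_dynamics: dict[str, Dynamics] = field(default_factory=dict)
    inoculated_genus: Optional[Inoculation] = None
    reads_per_sample: int = 1_000_000
    seed: int = 0
    background_pool: int = 200
    unannotated_gene_rate: float = 0.5
    pathway_overlap_rate: float = 0.0
    overdispersion: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise SpecError("n_pathways must be >= 1")
        lo, hi = self.kos_per_pathway
        if lo < 1 or hi < lo:
            raise SpecError(f"empty kos_per_pathway range {self.kos_per_pathway}")
        if self.reads_per_sample < 1:
            raise SpecError("reads_per_sample must be >= 1")
        if not 0 <= self.unannotated_gene_rate < 1:
            raise SpecError("unannotated_gene_rate must lie in [0, 1)")

    # -- genus weights ----------------------------------------------------

    def _weight(self, genus: str, sample: SampleSpec) -> float:
        dyn = self.genus_dynamics[genus]
        if isinstance(dyn, dict):
            if sample.class_label not in dyn:
                raise SpecError(
                    f"dynamics of genus {genus!r} lack class {sample.class_label!r}"
                )
            dyn = dyn[sample.class_label]
        if sample.timepoint >= len(dyn):
            raise SpecError(
                f"timepoint {sample.timepoint} outside dynamics of genus {genus!r}"
            )
        return float(dyn[sample.timepoint])

    def genus_weights(self, sample: SampleSpec) -> dict[str, float]:
        """Planted relative genus abundances for one sample, summing to 1.

        The base trajectory values must sum to 1 per sample within 1e-9;
        an inoculation boost is added on top and the vector renormalized.
        """
        w = {g: self._weight(g, sample) for g in sorted(self.genus_dynamics)}
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(
                f"genus abundances for sample {sample.name!r} sum to {total!r}, not 1"
            )
        if self.inoculated_genus and sample.name in self.inoculated_genus.samples:
            g = self.inoculated_genus.genus
            if g not in w:
                raise SpecError(f"inoculated genus {g!r} has no dynamics entry")
            w[g] += self.inoculated_genus.boost
            total = sum(w.values())
            w = {g_: v / total for g_, v in w.items()}
        return w

    # -- (de)serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "n_pathways": self.n_pathways,
            "kos_per_pathway": list(self.kos_per_pathway),
            "organisms": [
                {
                    "name": o.name,
                    "genus": o.genus,
                    "pathway_absences": sorted(o.pathway_absences),
                    "extra_ko_rate": o.extra_ko_rate,
                }
                for o in self.organisms
            ],
            "samples": [
                {
                    "name": s.name,
                    "class_label": s.class_label,
                    "timepoint": s.timepoint,
                    **({"variety": s.variety} if s.variety else {}),
                }
                for s in self.samples
            ],
            "genus_dynamics": {
                g: (
                    {c: list(v) for c, v in dyn.items()}
                    if isinstance(dyn, dict)
                    else list(dyn)
                )
                for g, dyn in self.genus_dynamics.items()
            },
            "inoculated_genus": (
                {
                    "genus": self.inoculated_genus.genus,
                    "samples": list(self.inoculated_genus.samples),
                    "boost": self.inoculated_genus.boost,
                }
                if self.inoculated_genus
                else None
            ),
            "reads_per_sample": self.reads_per_sample,
            "seed": self.seed,
            "background_pool": self.background_pool,
            "unannotated_gene_rate": self.unannotated_gene_rate,
            "pathway_overlap_rate": self.pathway_overlap_rate,
            "overdispersion": self.overdispersion,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CommunitySpec":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        inoc = doc.get("inoculated_genus")
        return cls(
            n_pathways=doc["n_pathways"],
            kos_per_pathway=tuple(doc["kos_per_pathway"]),
            organisms=[
                OrganismSpec(
                    name=o["name"],
                    genus=o["genus"],
                    pathway_absences=frozenset(o.get("pathway_absences", [])),
                    extra_ko_rate=o.get("extra_ko_rate", 0.0),
                )
                for o in doc.get("organisms", [])
            ],
            samples=[
                SampleSpec(
                    name=s["name"],
                    class_label=s["class_label"],
                    timepoint=s["timepoint"],
                    variety=s.get("variety"),
                )
                for s in doc.get("samples", [])
            ],
            genus_dynamics=doc.get("genus_dynamics", {}),
            inoculated_genus=(
                Inoculation(
                    genus=inoc["genus"],
                    samples=tuple(inoc["samples"]),
                    boost=inoc["boost"],
                )
                if inoc
                else None
            ),
            reads_per_sample=doc.get("reads_per_sample", 1_000_000),
            seed=doc.get("seed", 0),
            background_pool=doc.get("background_pool", 200),
            unannotated_gene_rate=doc.get("unannotated_gene_rate", 0.5),
            pathway_overlap_rate=doc.get("pathway_overlap_rate", 0.0),
            overdispersion=doc.get("overdispersion"),
        )


def _ko_id(i: int) -> str:
    if i > 99999:
        raise SpecError("KO id space exhausted")
    return f"K{i:05d}"


def make_ontology(spec: CommunitySpec) -> PathwayOntology:
    """Pathway ontology of disjoint KO blocks (sizes uniform in range).

    With ``pathway_overlap_rate > 0`` each pathway additionally adopts,
    per member slot, a KO from the other pathways with that probability —
    mimicking the overlap of real pathway maps at the cost of exact
    block structure.
    """
    rng = np.random.default_rng([spec.seed, 0])
    lo, hi = spec.kos_per_pathway
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    pathways: dict[str, Pathway] = {}
    counter = 1
    blocks: list[set[str]] = []
    for i, size in enumerate(sizes, start=1):
        members = {_ko_id(counter + j) for j in range(int(size))}
        counter += int(size)
        blocks.append(members)
        pathways[f"p{i:03d}"] = Pathway(name=f"pathway_{i}", members=frozenset(members))
    if spec.pathway_overlap_rate > 0:
        all_kos = sorted(set().union(*blocks))
        for i, pid in enumerate(sorted(pathways)):
            own = set(pathways[pid].members)
            foreign = [k for k in all_kos if k not in own]
            extra = {
                k
                for k in foreign
                if rng.random() < spec.pathway_overlap_rate
            }
            if extra:
                pathways[pid] = Pathway(
                    name=pathways[pid].name, members=frozenset(own | extra)
                )
    return PathwayOntology(pathways=pathways)


def make_isolates(
    spec: CommunitySpec, ont: PathwayOntology
) -> list[KoAnnotation]:
    """Annotation tables for the planted organisms.

    An organism carries every KO of every pathway outside its absence
    set (coverage exactly 1 there, 0 on absent pathways), plus background
    KOs drawn from a pool disjoint from the ontology at
    ``extra_ko_rate`` per pool member, plus unannotated filler genes at
    ``unannotated_gene_rate`` of the final gene count.
    """
    if not spec.organisms:
        raise SpecError("spec has no organisms")
    unknown = {
        p for o in spec.organisms for p in o.pathway_absences
    } - set(ont.pathways)
    if unknown:
        raise SpecError(f"pathway_absences reference unknown pathways: {sorted(unknown)}")
    pool = [_ko_id(90000 + i) for i in range(spec.background_pool)]
    out: list[KoAnnotation] = []
    for idx, org in enumerate(spec.organisms):
        rng = np.random.default_rng([spec.seed, 1, idx])
        kos: set[str] = set()
        for pid in ont.pathway_ids:
            if pid not in org.pathway_absences:
                kos |= ont.members(pid)
        if org.extra_ko_rate > 0:
            mask = rng.random(len(pool)) < org.extra_ko_rate
            kos |= {k for k, m in zip(pool, mask) if m}
        records = [
            GeneRecord(gene_id=f"{org.name}_g{i:05d}", ko=ko)
            for i, ko in enumerate(sorted(kos), start=1)
        ]
        rate = spec.unannotated_gene_rate
        n_unannot = int(round(len(records) * rate / (1.0 - rate))) if rate else 0
        records += [
            GeneRecord(gene_id=f"{org.name}_u{i:05d}", ko=None)
            for i in range(1, n_unannot + 1)
        ]
        out.append(KoAnnotation(unit_id=org.name, records=records))
    return out


def make_metagenome_series(
    spec: CommunitySpec, ont: PathwayOntology
) -> list[KoAnnotation]:
    """Per-sample (genus, KO) read tables drawn from planted dynamics.

    Each genus' KO repertoire is the union over the spec's organisms of
    that genus; within a genus reads spread uniformly over its KOs. Reads
    per sample are multinomial over all (genus, KO) cells with the
    sample's planted genus weights — or Dirichlet-multinomial when
    ``overdispersion`` (a concentration parameter; smaller = noisier) is
    set. The expected read share of a genus equals its planted relative
    abundance.
    """
    if not spec.samples:
        raise SpecError("spec has no samples")
    isolates = make_isolates(spec, ont)
    repertoire: dict[str, list[str]] = {}
    for org_spec, ann in zip(spec.organisms, isolates):
        merged = set(repertoire.get(org_spec.genus, [])) | ann.kos
        repertoire[org_spec.genus] = sorted(merged)
    missing = [g for g in spec.genus_dynamics if g not in repertoire]
    if missing:
        raise SpecError(f"genera with dynamics but no organism: {', '.join(missing)}")
    out: list[KoAnnotation] = []
    for s_idx, sample in enumerate(spec.samples):
        rng = np.random.default_rng([spec.seed, 2, s_idx])
        weights = spec.genus_weights(sample)
        genera = sorted(g for g, w in weights.items() if w > 0)
        if spec.overdispersion is not None:
            alpha = np.array([weights[g] for g in genera]) * spec.overdispersion
            drawn = rng.dirichlet(alpha)
            weights = dict(zip(genera, drawn))
        cells: list[tuple[str, str]] = []
        probs: list[float] = []
        for g in genera:
            kos = repertoire[g]
            share = weights[g] / len(kos)
            for ko in kos:
                cells.append((g, ko))
                probs.append(share)
        probs_arr = np.array(probs)
        probs_arr /= probs_arr.sum()
        counts = rng.multinomial(spec.reads_per_sample, probs_arr)
        records = [
            GeneRecord(
                gene_id=f"{sample.name}_o{i:06d}",
                ko=ko,
                genus=g,
                coverage=float(c),
            )
            for i, ((g, ko), c) in enumerate(zip(cells, counts), start=1)
            if c > 0
        ]
        out.append(KoAnnotation(unit_id=sample.name, records=records))
    return out


# ---------------------------------------------------------------------------
# Default study-shaped specifications
# ---------------------------------------------------------------------------

#: Planted isolate groups: (genus stem, number of organisms, absent pathways).
_ISOLATE_GROUPS: list[tuple[str, int, tuple[str, ...]]] = [
    ("Lactobacillus_a", 6, ("p001", "p002")),
    ("Lactobacillus_b", 5, ("p003", "p004")),
    ("Lactococcus", 4, ("p005", "p006")),
    ("Acetobacter", 4, ("p007", "p008")),
    ("Rothia", 3, ("p009", "p010")),
    ("Staphylococcus", 3, ("p011", "p012")),
    ("Micrococcus", 3, ("p013", "p014")),
    ("Saccharomyces", 2, ("p015", "p016")),
]


def default_isolate_spec(seed: int = 0, extra_ko_rate: float = 0.02) -> CommunitySpec:
    """A kefir-culture-shaped isolate community: 30 organisms in 8 groups.

    Eight groups of organisms (mirroring the genus-level grouping of a
    kefir culture) each miss a private pair of pathways out of 20, so the
    KO-presence matrix has 8 well-separated planted clusters and every
    absent pathway is a planted auxotrophy signal.
    """
    organisms = [
        OrganismSpec(
            name=f"{stem}_{i}",
            genus=stem.split("_")[0],
            pathway_absences=frozenset(absences),
            extra_ko_rate=extra_ko_rate,
        )
        for stem, count, absences in _ISOLATE_GROUPS
        for i in range(1, count + 1)
    ]
    return CommunitySpec(
        n_pathways=20,
        kos_per_pathway=(5, 15),
        organisms=organisms,
        seed=seed,
    )


def default_metagenome_spec(
    seed: int = 0,
    n_timepoints: int = 4,
    fermentations_per_class: int = 3,
    reads_per_sample: int = 1_000_000,
) -> CommunitySpec:
    """A wine-fermentation-shaped inoculation series.

    Two classes of fermentations — ``treated`` (inoculated with
    *Lactobacillus*) and ``control`` — each with several replicate
    fermentations sampled over time. The inoculated genus is boosted in
    the treated samples; two mold genera are suppressed there (the
    knock-on signal that survives complement adjustment), and the
    remaining genera follow shared fermentation dynamics (yeast rising,
    early colonists declining).
    """

    def tp(values: Sequence[float]) -> list[float]:
        if len(values) != n_timepoints:
            # linear resample of the 4-point template onto n_timepoints
            x = np.linspace(0, 1, len(values))
            xi = np.linspace(0, 1, n_timepoints)
            return list(np.interp(xi, x, values))
        return list(values)

    # 4-point abundance templates per genus and class. The planted class
    # signal lives in class-exclusive genera (Pantoea/Gluconobacter in
    # treated, Dyella in control, molds suppressed under treatment) on
    # top of the inoculated Lactobacillus, so it survives complement
    # adjustment; shared fermentation trends (yeast rising, early
    # colonists declining) are deliberately mild in comparison.
    templates = {
        "Saccharomyces": ([0.40, 0.45, 0.50, 0.52], [0.42, 0.47, 0.52, 0.54]),
        "Pseudomonas": ([0.12, 0.08, 0.05, 0.04], [0.13, 0.09, 0.06, 0.05]),
        "Vitis": ([0.08, 0.06, 0.04, 0.03], [0.09, 0.07, 0.05, 0.04]),
        "Oenococcus": ([0.05, 0.07, 0.09, 0.10], [0.05, 0.07, 0.09, 0.10]),
        "Lactobacillus": ([0.15, 0.18, 0.20, 0.20], [0.02, 0.015, 0.01, 0.01]),
        "Pantoea": ([0.10, 0.09, 0.07, 0.06], [0.005, 0.003, 0.002, 0.002]),
        "Gluconobacter": ([0.06, 0.05, 0.04, 0.04], [0.003, 0.002, 0.002, 0.002]),
        "Aspergillus": ([0.025, 0.013, 0.005, 0.005], [0.14, 0.13, 0.12, 0.11]),
        "Sclerotinia": ([0.015, 0.007, 0.005, 0.005], [0.09, 0.08, 0.075, 0.07]),
        "Dyella": ([0.01, 0.005, 0.001, 0.001], [0.06, 0.05, 0.045, 0.04]),
    }
    genus_dynamics: dict[str, Dynamics] = {
        g: {"treated": tp(tr), "control": tp(co)}
        for g, (tr, co) in templates.items()
    }
    # renormalize each (class, timepoint) column to sum exactly to 1
    for ci, cls in enumerate(("treated", "control")):
        for t in range(n_timepoints):
            total = sum(dyn[cls][t] for dyn in genus_dynamics.values())
            for dyn in genus_dynamics.values():
                dyn[cls][t] /= total

    genera = sorted(genus_dynamics)
    organisms = [
        OrganismSpec(
            name=f"{g}_ref",
            genus=g,
            pathway_absences=frozenset([f"p{(2 * i) % 20 + 1:03d}"]),
            extra_ko_rate=0.0,
        )
        for i, g in enumerate(genera)
    ]
    samples = [
        SampleSpec(
            name=f"{cls}_f{f}_t{t}",
            class_label=cls,
            timepoint=t,
        )
        for cls in ("treated", "control")
        for f in range(1, fermentations_per_class + 1)
        for t in range(n_timepoints)
    ]
    inoculation = Inoculation(
        genus="Lactobacillus",
        samples=tuple(s.name for s in samples if s.class_label == "treated"),
        boost=0.15,
    )
    return CommunitySpec(
        n_pathways=20,
        kos_per_pathway=(5, 15),
        organisms=organisms,
        samples=samples,
        genus_dynamics=genus_dynamics,
        inoculated_genus=inoculation,
        reads_per_sample=reads_per_sample,
        seed=seed,
    )
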