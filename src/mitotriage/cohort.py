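"""Cohort manifest: the planted-truth description of every family.

A manifest row is one family and one unit of the diagnostic-yield
denominator.  Each family carries a triage strategy (A: consanguineous
and/or more than one affected patient, filtered for recessive/X-linked
inheritance; B: single patient from non-consanguineous parents,
additionally screened for dominant variants in a predefined gene set), a
clinical group (1: probable/definite mitochondrial disease by MDC score;
2: possible), and optionally a planted causal defect — an mtDNA point
mutation, a single large mtDNA deletion, or one or more nuclear gene
defects with an inheritance mode.  Secondary mtDNA findings (multiple
deletions, depletion) escalate a family to exome analysis without solving
it at the mtDNA stage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

MT_CATEGORIES = {"mt_point", "mt_single_deletion", "mt_multiple_deletions", "mt_depletion"}
NUCLEAR_CATEGORIES = {
    "nuclear_AR_hom",
    "nuclear_AR_comphet",
    "nuclear_XLR",
    "nuclear_XLD_denovo",
    "nuclear_AD_denovo",
    "nuclear_AD_inherited",
}
CATEGORIES = MT_CATEGORIES | NUCLEAR_CATEGORIES | {"none"}

GENE_MODES = {"AR_hom", "AR_comphet", "XLR", "XLD_denovo", "AD_denovo", "AD_inherited", "AD_unknown"}

#: Causal genes on the X chromosome (everything else is autosomal).
X_LINKED_GENES = {"SLC16A2", "TAZ", "WDR45", "CASK"}


class ManifestError(ValueError):
    """Raised for malformed or invariant-violating manifest input."""


@dataclass(frozen=True)
class MemberSpec:
    member_id: str
    sex: str  # "m" | "f"
    affected: bool
    father_id: str | None = None
    mother_id: str | None = None
    subclinical: bool = False


@dataclass(frozen=True)
class PlantedGene:
    """One causal gene of a (possibly multi-genic) planted defect."""

    gene: str
    mode: str  # member of GENE_MODES
    mitocarta: bool


@dataclass(frozen=True)
class PlantedDefect:
    category: str
    genes: tuple[PlantedGene, ...] = ()
    mt_allele: str | None = None  # e.g. "m.3243A>G"
    heteroplasmy: float | None = None  # 1.0 for homoplasmic
    breakpoints: tuple[int, int] | None = None  # (b5, b3), 1-based rCRS

    def __post_init__(self):
        if self.category not in CATEGORIES - {"none"}:
            raise ManifestError(f"unknown defect category {self.category!r}")
        if self.heteroplasmy is not None and not 0.0 <= self.heteroplasmy <= 1.0:
            raise ManifestError(f"heteroplasmy {self.heteroplasmy} outside [0, 1]")
        if self.breakpoints is not None:
            b5, b3 = self.breakpoints
            if not (1 <= b5 < b3 <= 16569):
                raise ManifestError(f"breakpoints {self.breakpoints} invalid")


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    strategy: str  # "A" | "B"
    consanguineous: bool
    n_affected: int
    group: int  # 1 | 2 (as printed; never recomputed from the MDC score)
    mdc_score: int
    members: tuple[MemberSpec, ...]
    planted: PlantedDefect | None = None
    mt_secondary: str = "none"  # none | multiple_deletions | depletion
    syndrome: str = ""
    parents_available: bool = True

    def __post_init__(self):
        if self.strategy not in ("A", "B"):
            raise ManifestError(f"{self.family_id}: strategy must be A or B")
        if self.strategy == "A" and not (self.consanguineous or self.n_affected > 1):
            raise ManifestError(
                f"{self.family_id}: strategy A requires consanguinity or >1 affected"
            )
        if self.strategy == "B" and (self.consanguineous or self.n_affected != 1):
            raise ManifestError(
                f"{self.family_id}: strategy B requires a single non-consanguineous patient"
            )

    @property
    def affected(self) -> tuple[MemberSpec, ...]:
        return tuple(m for m in self.members if m.affected)

    @property
    def unaffected(self) -> tuple[MemberSpec, ...]:
        return tuple(m for m in self.members if not m.affected)


@dataclass
class CohortManifest:
    families: list[FamilySpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    @property
    def n_mt_defects(self) -> int:
        return sum(
            1 for f in self.families if f.planted and f.planted.category in MT_CATEGORIES
        )

    @property
    def n_nuclear_defects(self) -> int:
        return sum(
            1 for f in self.families if f.planted and f.planted.category in NUCLEAR_CATEGORIES
        )

    @property
    def n_defect_free(self) -> int:
        return sum(1 for f in self.families if f.planted is None)

    def validate_totals(self, expected: dict[str, int]) -> None:
        """Check declared cohort totals (e.g. {"families": 117, "mt": 23})."""
        actual = {
            "families": len(self),
            "mt": self.n_mt_defects,
            "nuclear": self.n_nuclear_defects,
            "none": self.n_defect_free,
        }
        for key, want in expected.items():
            if actual[key] != want:
                raise ManifestError(f"manifest {key} count {actual[key]} != declared {want}")


_COLUMNS = [
    "family_id", "strategy", "consanguineous", "n_affected", "sex_affected",
    "group", "mdc_score", "category", "syndrome", "mt_allele", "heteroplasmy",
    "breakpoints", "genes", "modes", "mitocarta", "mt_secondary",
    "subclinical_parent", "parents_available",
]


def _build_members(
    fid: str, n_affected: int, sex_first: str, parents_available: bool, subclinical: bool
) -> tuple[MemberSpec, ...]:
    father = f"{fid}_FA"
    mother = f"{fid}_MO"
    members = []
    for i in range(n_affected):
        sex = sex_first if i == 0 else ("m" if i % 2 else "f")
        members.append(
            MemberSpec(
                member_id=f"{fid}_P{i + 1}",
                sex=sex,
                affected=True,
                father_id=father if parents_available else None,
                mother_id=mother if parents_available else None,
            )
        )
    if parents_available:
        members.append(MemberSpec(father, "m", False, subclinical=subclinical))
        members.append(MemberSpec(mother, "f", False))
    return tuple(members)


def _parse_row(row: dict[str, str], lineno: int) -> FamilySpec:
    def blank(v: str) -> bool:
        return v in ("", ".")

    try:
        fid = row["family_id"]
        category = row["category"]
        if category not in CATEGORIES:
            raise ManifestError(f"unknown category {category!r}")
        parents_available = row["parents_available"] == "yes"
        subclinical = row["subclinical_parent"] == "yes"
        members = _build_members(
            fid, int(row["n_affected"]), row["sex_affected"], parents_available, subclinical
        )
        planted: PlantedDefect | None = None
        if category != "none":
            heteroplasmy = None
            if not blank(row["heteroplasmy"]):
                h = row["heteroplasmy"]
                heteroplasmy = 1.0 if h == "homoplasmic" else float(h)
            breakpoints = None
            if not blank(row["breakpoints"]):
                b5, b3 = row["breakpoints"].split(":")
                breakpoints = (int(b5), int(b3))
            genes: tuple[PlantedGene, ...] = ()
            if not blank(row["genes"]):
                names = row["genes"].split(";")
                modes = row["modes"].split(";")
                carta = row["mitocarta"].split(";")
                if not len(names) == len(modes) == len(carta):
                    raise ManifestError("genes/modes/mitocarta lists differ in length")
                for mode in modes:
                    if mode not in GENE_MODES:
                        raise ManifestError(f"unknown gene mode {mode!r}")
                genes = tuple(
                    PlantedGene(g, m, c == "yes") for g, m, c in zip(names, modes, carta)
                )
            planted = PlantedDefect(
                category=category,
                genes=genes,
                mt_allele=None if blank(row["mt_allele"]) else row["mt_allele"],
                heteroplasmy=heteroplasmy,
                breakpoints=breakpoints,
            )
        return FamilySpec(
            family_id=fid,
            strategy=row["strategy"],
            consanguineous=row["consanguineous"] == "yes",
            n_affected=int(row["n_affected"]),
            group=int(row["group"]),
            mdc_score=int(row["mdc_score"]),
            members=members,
            planted=planted,
            mt_secondary=row["mt_secondary"],
            syndrome=row["syndrome"],
            parents_available=parents_available,
        )
    except ManifestError as exc:
        raise ManifestError(f"manifest line {lineno}: {exc}") from None
    except (KeyError, ValueError) as exc:
        raise ManifestError(f"manifest line {lineno}: malformed row ({exc})") from None


def parse_manifest_text(text: str) -> CohortManifest:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return CohortManifest([])
    header = lines[0].rstrip("\n").split("\t")
    if header != _COLUMNS:
        raise ManifestError(f"manifest header mismatch: {header[:3]}...")
    families = []
    for lineno, line in enumerate(lines[1:], start=2):
        values = line.rstrip("\n").split("\t")
        if len(values) != len(header):
            raise ManifestError(f"manifest line {lineno}: {len(values)} fields, expected {len(header)}")
        families.append(_parse_row(dict(zip(header, values)), lineno))
    return CohortManifest(families)


def load_manifest(path) -> CohortManifest:
    """Load a cohort manifest from a TSV file."""
    with open(path) as fh:
        return parse_manifest_text(fh.read())


def paper_cohort() -> CohortManifest:
    """The packaged 117-family manifest transcribed from the study tables.

    Invariants: 117 families; 23 mtDNA defects, 57 nuclear defects, 37
    defect-free; 42 strategy-A units (2 mtDNA + 40 entering exome analysis)
    and 75 strategy-B units (21 mtDNA + 54 entering exome analysis).
    """
    text = (
        importlib.resources.files("mitotriage.data")
        .joinpath("cohort_manifest.tsv")
        .read_text()
    )
    manifest = parse_manifest_text(text)
    manifest.validate_totals({"families": 117, "mt": 23, "nuclear": 57, "none": 37})
    return manifest


def load_gene_panel(path_or_name) -> frozenset[str]:
    """Load a newline-delimited gene panel (file path or packaged name)."""
    try:
        text = (
            importlib.resources.files("mitotriage.data").joinpath(str(path_or_name)).read_text()
        )
    except FileNotFoundError:
        with open(path_or_name) as fh:
            text = fh.read()
    return frozenset(
        ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    )


def mitocarta_panel() -> frozenset[str]:
    return load_gene_panel("mitocarta_panel.txt")


def omim_dominant_panel() -> frozenset[str]:
    return load_gene_panel("omim_dominant_panel.txt")
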