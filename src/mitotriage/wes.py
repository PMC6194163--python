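"""Inheritance-model exome variant filtering and family diagnosis.

The cascade mirrors diagnostic practice for suspected mitochondrial and
neuromuscular disease: rare variants (population allele frequency < 1%;
non-annotated variants kept unless above 5% in the in-house database) with
a plausible effect (nonsense/frameshift/splice always; missense with at
least one damaging in-silico prediction) are matched against the
inheritance models the family structure supports — autosomal-recessive
homozygous, compound-heterozygous and X-linked recessive for every family,
plus heterozygous dominant/de novo variants restricted to an OMIM-derived
dominant-disease gene set for single patients from non-consanguineous
families.  Candidates must segregate with disease; a family is solved when
a segregating candidate carries a class 4/5 (likely/definitely pathogenic)
annotation.  Runs of homozygosity rank recessive candidates but never
exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import FamilySpec
from .roh import ROHRegion

EFFECT_CLASSES = {"missense", "nonsense", "frameshift", "splice", "synonymous", "other"}
LOF_EFFECTS = {"nonsense", "frameshift", "splice"}

DEFAULT_POPMAX = 0.01  # strict <
DEFAULT_INHOUSE_MAX = 0.05  # inclusive <=
DEFAULT_MIN_DAMAGING = 1
SOLVING_CLASSES = {4, 5}


@dataclass(frozen=True)
class NuclearVariant:
    """An annotated exome variant shared by all members of one family."""

    variant_id: str
    gene: str
    chromosome: str  # "1".."22" or "X"
    position: int
    ref: str
    alt: str
    effect: str  # member of EFFECT_CLASSES
    population_af: float | None  # None = not annotated
    inhouse_af: float
    n_damaging: int  # damaging calls among 4 independent predictors (0..4)
    acmg_class: int  # 1..5, consumed as an annotation
    mitocarta: bool
    omim_dominant: bool

    def __post_init__(self):
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect!r}")
        for af in (self.population_af, self.inhouse_af):
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} outside [0, 1]")

    @property
    def is_x(self) -> bool:
        return self.chromosome == "X"


#: genotypes: hom_ref | het | hom_alt | hemi | missing
FamilyGenotypes = dict[str, dict[str, str]]  # variant_id -> member_id -> genotype


@dataclass(frozen=True)
class CandidateSet:
    mode: str  # AR_hom | AR_comphet | XLR | XLD | AD
    variants: tuple[NuclearVariant, ...]
    gene: str
    in_roh: bool = False
    de_novo: bool | None = None  # None = unknown (parental data missing)
    unphasable: bool = False
    inherited_from: str | None = None  # member id of a transmitting parent (AD)


@dataclass(frozen=True)
class DiagnosisResult:
    family_id: str
    solved: bool
    stage: str  # "mtDNA" | "WES"
    genes: tuple[str, ...] = ()
    modes: tuple[str, ...] = ()
    mitocarta_flags: tuple[bool, ...] = ()
    de_novo: bool = False
    multi_genic: bool = False
    candidates: tuple[CandidateSet, ...] = ()
    mt_outcome: str = ""
    mt_variant: str = ""  # solving point mutation, e.g. "m.3243A>G"
    mt_label: str = ""  # syndrome label of a solving known point mutation
    mt_deletion: tuple[int, int] | None = None


def frequency_filter(
    variants,
    popmax: float = DEFAULT_POPMAX,
    inhouse_max: float = DEFAULT_INHOUSE_MAX,
) -> list[NuclearVariant]:
    """Keep rare variants: annotated ones with population AF strictly below
    ``popmax``; non-annotated ones unless their in-house frequency exceeds
    ``inhouse_max``."""
    if not 0 < popmax <= 1 or not 0 < inhouse_max <= 1:
        raise ValueError("frequency thresholds must be in (0, 1]")
    kept = []
    for v in variants:
        if v.population_af is not None:
            if v.population_af < popmax:
                kept.append(v)
        elif v.inhouse_af <= inhouse_max:
            kept.append(v)
    return kept


def effect_filter(variants, min_damaging: int = DEFAULT_MIN_DAMAGING) -> list[NuclearVariant]:
    """Keep loss-of-function variants unconditionally and missense variants
    with at least ``min_damaging`` damaging predictor calls."""
    if not 0 <= min_damaging <= 4:
        raise ValueError("min_damaging must be in 0..4")
    kept = []
    for v in variants:
        if v.effect in LOF_EFFECTS:
            kept.append(v)
        elif v.effect == "missense" and v.n_damaging >= min_damaging:
            kept.append(v)
    return kept


def _gt(genotypes: FamilyGenotypes, variant_id: str, member_id: str) -> str:
    return genotypes.get(variant_id, {}).get(member_id, "missing")


def _carries(gt: str) -> bool:
    return gt in ("het", "hom_alt", "hemi")


def recessive_candidates(
    family: FamilySpec,
    variants,
    genotypes: FamilyGenotypes,
    roh: list[ROHRegion] | None = None,
) -> list[CandidateSet]:
    """Autosomal-recessive homozygous, compound-heterozygous and X-linked
    recessive candidates from frequency- and effect-filtered variants.

    Candidates falling inside a run of homozygosity are ranked first (the
    run is a prioritisation signal, not a hard filter, so compound
    heterozygotes outside runs survive even in consanguineous families).
    Compound-heterozygous pairs whose phase cannot be resolved from
    parental genotypes are retained with an ``unphasable`` flag.
    """
    roh = roh or []
    affected = family.affected
    unaffected = family.unaffected
    candidates: list[CandidateSet] = []

    def in_roh(v: NuclearVariant) -> bool:
        return any(r.contains(v.chromosome, v.position) for r in roh)

    # AR homozygous
    for v in variants:
        if v.is_x:
            continue
        if all(_gt(genotypes, v.variant_id, m.member_id) == "hom_alt" for m in affected) and not any(
            _gt(genotypes, v.variant_id, m.member_id) == "hom_alt" for m in unaffected
        ):
            candidates.append(CandidateSet("AR_hom", (v,), v.gene, in_roh=in_roh(v)))

    # AR compound heterozygous: >=2 heterozygous variants in one gene in trans
    by_gene: dict[str, list[NuclearVariant]] = {}
    for v in variants:
        if v.is_x:
            continue
        if all(_gt(genotypes, v.variant_id, m.member_id) == "het" for m in affected):
            by_gene.setdefault(v.gene, []).append(v)
    for gene, gene_variants in by_gene.items():
        for i in range(len(gene_variants)):
            for j in range(i + 1, len(gene_variants)):
                v1, v2 = gene_variants[i], gene_variants[j]
                phase = _phase_pair(family, genotypes, v1, v2)
                if phase == "cis":
                    continue
                candidates.append(
                    CandidateSet(
                        "AR_comphet",
                        (v1, v2),
                        gene,
                        in_roh=in_roh(v1) and in_roh(v2),
                        unphasable=phase == "unknown",
                    )
                )

    # X-linked recessive: hemizygous variant in affected males
    affected_males = [m for m in affected if m.sex == "m"]
    for v in variants:
        if not v.is_x or not affected_males:
            continue
        if all(
            _gt(genotypes, v.variant_id, m.member_id) in ("hemi", "hom_alt")
            for m in affected_males
        ) and all(_carries(_gt(genotypes, v.variant_id, m.member_id)) for m in affected):
            if any(
                _gt(genotypes, v.variant_id, m.member_id) in ("hemi", "hom_alt")
                for m in unaffected
            ):
                continue
            candidates.append(CandidateSet("XLR", (v,), v.gene, in_roh=in_roh(v)))

    candidates.sort(key=lambda c: (not c.in_roh, c.gene, c.mode))
    return candidates


def _phase_pair(family, genotypes, v1, v2) -> str:
    """Phase two heterozygous variants from parental genotypes: 'trans',
    'cis' or 'unknown'."""
    proband = family.affected[0]
    if proband.father_id is None or proband.mother_id is None:
        return "unknown"
    origins = []
    for v in (v1, v2):
        fa = _gt(genotypes, v.variant_id, proband.father_id)
        mo = _gt(genotypes, v.variant_id, proband.mother_id)
        if fa == "missing" or mo == "missing":
            return "unknown"
        fa_c, mo_c = _carries(fa), _carries(mo)
        if fa_c and not mo_c:
            origins.append("father")
        elif mo_c and not fa_c:
            origins.append("mother")
        elif not fa_c and not mo_c:
            origins.append("denovo")
        else:
            return "unknown"
    if "denovo" in origins:
        return "trans"  # a de novo het cannot be in cis with an inherited one for sure; treat as trans-compatible
    return "trans" if origins[0] != origins[1] else "cis"


def dominant_candidates(
    family: FamilySpec,
    variants,
    genotypes: FamilyGenotypes,
    omim_ad_genes: frozenset[str],
) -> list[CandidateSet]:
    """Heterozygous dominant candidates for single patients from
    non-consanguineous families (strategy B), restricted to the
    OMIM-derived dominant-disease gene set.

    A variant absent from both parents is flagged de novo; one present in a
    parent is retained but flagged inherited (the transmitting parent may
    show subclinical symptoms); missing parental genotypes leave the de
    novo status unknown.
    """
    if family.strategy != "B":
        raise ValueError("dominant filtering applies to strategy-B families only")
    proband = family.affected[0]
    candidates = []
    for v in variants:
        if v.gene not in omim_ad_genes:
            continue
        gt = _gt(genotypes, v.variant_id, proband.member_id)
        if gt not in ("het", "hemi"):
            continue
        mode = "XLD" if v.is_x else "AD"
        if proband.father_id is None or proband.mother_id is None:
            de_novo, origin = None, None
        else:
            fa = _gt(genotypes, v.variant_id, proband.father_id)
            mo = _gt(genotypes, v.variant_id, proband.mother_id)
            if fa == "missing" or mo == "missing":
                de_novo, origin = None, None
            elif not _carries(fa) and not _carries(mo):
                de_novo, origin = True, None
            else:
                de_novo = False
                origin = proband.father_id if _carries(fa) else proband.mother_id
        candidates.append(
            CandidateSet(mode, (v,), v.gene, de_novo=de_novo, inherited_from=origin)
        )
    return candidates


def segregation_check(
    candidate: CandidateSet, family: FamilySpec, genotypes: FamilyGenotypes
) -> bool:
    """True when every affected member carries the candidate genotype and no
    unaffected member carries a disease-consistent genotype under the
    candidate's mode.  Members with missing genotypes are not evaluated.
    A dominant variant transmitted by a parent fails unless that parent is
    flagged subclinical."""
    affected = family.affected
    unaffected = family.unaffected
    mode = candidate.mode

    if mode == "AR_hom":
        v = candidate.variants[0]
        for m in affected:
            if _gt(genotypes, v.variant_id, m.member_id) not in ("hom_alt", "missing"):
                return False
        return not any(
            _gt(genotypes, v.variant_id, m.member_id) == "hom_alt" for m in unaffected
        )

    if mode == "AR_comphet":
        for m in affected:
            for v in candidate.variants:
                if _gt(genotypes, v.variant_id, m.member_id) not in ("het", "hom_alt", "missing"):
                    return False
        for m in unaffected:
            if all(
                _carries(_gt(genotypes, v.variant_id, m.member_id))
                for v in candidate.variants
            ):
                return False
        return True

    if mode == "XLR":
        v = candidate.variants[0]
        for m in affected:
            gt = _gt(genotypes, v.variant_id, m.member_id)
            want = ("hemi", "hom_alt", "missing") if m.sex == "m" else ("het", "hom_alt", "hemi", "missing")
            if gt not in want:
                return False
        for m in unaffected:
            gt = _gt(genotypes, v.variant_id, m.member_id)
            if m.sex == "m" and gt in ("hemi", "hom_alt"):
                return False
            if m.sex == "f" and gt == "hom_alt":
                return False
        return True

    if mode in ("AD", "XLD"):
        v = candidate.variants[0]
        for m in affected:
            if _gt(genotypes, v.variant_id, m.member_id) not in ("het", "hemi", "hom_alt", "missing"):
                return False
        for m in unaffected:
            if _carries(_gt(genotypes, v.variant_id, m.member_id)) and not m.subclinical:
                return False
        return True

    raise ValueError(f"unknown candidate mode {mode!r}")


def diagnose_family(
    family: FamilySpec,
    candidates,
    genotypes: FamilyGenotypes,
    mitocarta: frozenset[str],
) -> DiagnosisResult:
    """Reduce segregation-checked candidates to a per-family diagnosis.

    A family is solved when at least one segregating candidate consists
    solely of class-4/5 variants; candidates in several genes are all
    reported and the family is flagged multi-genic.  Lower-class
    candidates are variants of unknown significance and never solve."""
    passing = []
    for cand in candidates:
        if not segregation_check(cand, family, genotypes):
            continue
        if not all(v.acmg_class in SOLVING_CLASSES for v in cand.variants):
            continue
        passing.append(cand)
    # one candidate per gene (an ROH-ranked duplicate never adds a gene)
    seen: dict[str, CandidateSet] = {}
    for cand in passing:
        seen.setdefault(cand.gene, cand)
    genes = tuple(seen)
    modes = tuple(seen[g].mode for g in genes)
    return DiagnosisResult(
        family_id=family.family_id,
        solved=bool(genes),
        stage="WES",
        genes=genes,
        modes=modes,
        mitocarta_flags=tuple(g in mitocarta for g in genes),
        de_novo=any(seen[g].de_novo is True for g in genes),
        multi_genic=len(genes) > 1,
        candidates=tuple(passing),
    )


def filter_cascade(
    variants,
    popmax: float = DEFAULT_POPMAX,
    inhouse_max: float = DEFAULT_INHOUSE_MAX,
    min_damaging: int = DEFAULT_MIN_DAMAGING,
) -> list[NuclearVariant]:
    """Frequency filter followed by effect filter (the two commute)."""
    return effect_filter(
        frequency_filter(variants, popmax=popmax, inhouse_max=inhouse_max),
        min_damaging=min_damaging,
    )
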