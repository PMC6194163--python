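"""Synthetic per-family inputs for the two-step diagnostic pipeline.

Every family in a cohort manifest is expanded into the raw inputs the
callers consume: an mtDNA pileup/read set (binomially sampled heteroplasmy
for point variants; junction-spanning reads for large deletions), a qPCR
copy-number record with a healthy-control set, SNP genotype tracks for
homozygosity mapping, and an annotated exome variant table with
per-member genotypes.

Planted truth is a deterministic function of the manifest alone: causal
variants (identity, zygosity, annotations) are derived from stable hashes
of the gene names, so re-seeding changes read noise, background variants
and control values but never the defect a family carries.  Background
exome variants are drawn from a synthetic gene universe and constructed to
be removed by the filter cascade (common, benign-predicted, synonymous,
segregation-inconsistent, or outside the dominant gene panel), emulating
the bulk of an exome that the filters must dispose of.

Reads are emitted in aligned coordinates (alignment itself is out of
scope); junction reads carry unaligned status so the deletion caller must
place them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .cohort import X_LINKED_GENES, FamilySpec
from .mtdna import MtPileup, MtRead
from .refseq import MT_LENGTH, PINNED_JUNCTIONS, mt_reference
from .wes import FamilyGenotypes, NuclearVariant


@dataclass(frozen=True)
class SimulationConfig:
    mt_depth: int = 1000  # mean mtDNA read depth per site
    read_length: int = 300  # nt, emulating 2x300 paired-end chemistry
    base_error_rate: float = 0.0  # per-base; 0 keeps cutoff decisions noise-free
    junction_reads: int = 50  # junction-spanning reads per deletion event
    background_variants_per_exome: int = 120
    n_controls: int = 10  # healthy controls in the qPCR normalisation set
    seed: int = 0

    def __post_init__(self):
        for name in ("mt_depth", "read_length", "junction_reads", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.background_variants_per_exome < 0:
            raise ValueError("background_variants_per_exome must be >= 0")


#: junctions used for families whose secondary mtDNA finding is multiple
#: deletions (two distinct events, both inside the major arc; the last two
#: repeat-free junctions pinned into the reference)
MULTIPLE_DELETION_JUNCTIONS = PINNED_JUNCTIONS[3:]

_BASES = "ACGT"


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


def family_rng(family_id: str, seed: int, stream: str = "") -> np.random.Generator:
    """Deterministic per-family random generator (independent across
    families and streams, fully determined by the run seed)."""
    return np.random.default_rng([seed % (2**31), _crc(family_id), _crc(stream)])


def parse_mt_allele(allele: str) -> tuple[int, str, str]:
    """Parse an allele label like ``m.3243A>G`` into (position, ref, alt)."""
    body = allele.removeprefix("m.")
    ref_alt = body.rstrip()
    pos = int("".join(ch for ch in ref_alt if ch.isdigit()))
    ref, alt = ref_alt[len(str(pos)) :].split(">")
    return pos, ref, alt


# ---------------------------------------------------------------------------
# mtDNA reads and pileups


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    for i in np.flatnonzero(rng.random(len(arr)) < rate):
        arr[i] = _BASES[(_BASES.index(arr[i]) + rng.integers(1, 4)) % 4]
    return "".join(arr)


def generate_mt_reads(
    family: FamilySpec, cfg: SimulationConfig
) -> tuple[list[MtRead], list[MtPileup], dict]:
    """Simulate the mtDNA sequencing output for one family.

    Point variants appear in the pileup with alternate depth drawn
    Binomial(depth, heteroplasmy); deletions produce ``cfg.junction_reads``
    unaligned reads concatenating reference up to b5 with reference from
    b3 (split position uniform across the read); depletion affects only
    the qPCR record.  Families whose secondary finding is multiple
    deletions receive junction reads for two distinct events.
    """
    planted = family.planted
    category = planted.category if planted else "none"
    if category.startswith("nuclear") or category == "none":
        pass
    elif not category.startswith("mt_"):
        raise ValueError(f"{family.family_id}: not an mtDNA category: {category}")
    rng = family_rng(family.family_id, cfg.seed, "mt")
    ref = mt_reference()
    truth: dict = {"family_id": family.family_id, "category": category}

    pileups: list[MtPileup] = []
    reads: list[MtRead] = []

    # a few reference-only monitoring positions (incl. one D-loop position)
    for pos in (1200, 4500, 9000, 14000, 16100):
        pileups.append(MtPileup(pos, ref[pos - 1], {ref[pos - 1]: int(cfg.mt_depth)}))

    if category == "mt_point":
        pos, vref, valt = parse_mt_allele(planted.mt_allele)
        if ref[pos - 1] != vref:
            raise ValueError(f"reference allele mismatch at m.{pos}")
        h = planted.heteroplasmy
        if h is None or not 0.0 <= h <= 1.0:
            raise ValueError(f"{family.family_id}: heteroplasmy {h} outside [0, 1]")
        depth = int(cfg.mt_depth)
        alt_depth = int(rng.binomial(depth, h))
        pileups.append(MtPileup(pos, vref, {valt: alt_depth, vref: depth - alt_depth}))
        truth.update(allele=planted.mt_allele, heteroplasmy=h, alt_depth=alt_depth, depth=depth)

    junctions: list[tuple[int, int]] = []
    if category == "mt_single_deletion":
        junctions = [planted.breakpoints]
    elif family.mt_secondary == "multiple_deletions":
        junctions = list(MULTIPLE_DELETION_JUNCTIONS)
    for b5, b3 in junctions:
        if not (1 <= b5 < b3 <= MT_LENGTH):
            raise ValueError(f"breakpoints {(b5, b3)} outside the reference")
        n_reads = max(cfg.junction_reads // len(junctions), 1)
        for i in range(n_reads):
            split = int(rng.integers(25, cfg.read_length - 25 + 1))
            prefix = ref[b5 - split : b5]
            suffix = ref[b3 - 1 : b3 - 1 + (cfg.read_length - split)]
            seq = _apply_errors(prefix + suffix, cfg.base_error_rate, rng)
            reads.append(MtRead(f"{family.family_id}_junc_{b5}_{b3}_{i}", seq, None))
    truth["junctions"] = junctions

    # a handful of ordinary aligned reads for provenance
    for i in range(5):
        start = int(rng.integers(1, MT_LENGTH - cfg.read_length))
        seq = _apply_errors(
            ref[start - 1 : start - 1 + cfg.read_length], cfg.base_error_rate, rng
        )
        reads.append(MtRead(f"{family.family_id}_ref_{i}", seq, start))

    pileups.sort(key=lambda p: p.position)
    return reads, pileups, truth


def generate_qpcr(family: FamilySpec, cfg: SimulationConfig) -> tuple[float, list[float], dict]:
    """mt/nuclear copy-number ratio for the proband plus a control set.

    Depletion families sit at 12-28% of the control mean (inside the
    10-30% band reported for depletion syndromes); all others near 100%.
    """
    rng = family_rng(family.family_id, cfg.seed, "qpcr")
    controls = list(np.clip(rng.normal(1.0, 0.05, cfg.n_controls), 0.5, None))
    depleted = (
        family.mt_secondary == "depletion"
        or (family.planted is not None and family.planted.category == "mt_depletion")
    )
    if depleted:
        factor = float(rng.uniform(0.12, 0.28))
    else:
        factor = float(np.clip(rng.normal(1.0, 0.05), 0.5, None))
    ratio = factor * float(np.mean(controls))
    return ratio, controls, {"depleted": depleted, "factor": factor}


# ---------------------------------------------------------------------------
# nuclear gene universe


def gene_locus(gene: str) -> tuple[str, int]:
    """Deterministic synthetic locus for a gene: chromosome and 1-based
    start of a 100 kb span on a 150 Mb chromosome canvas."""
    if gene in X_LINKED_GENES:
        code = _crc("X:" + gene)
        return "X", 10_000_000 + code % 130_000_000
    code = _crc(gene)
    return str(code % 22 + 1), 10_000_000 + (code >> 5) % 130_000_000


def _hash_variant(gene: str, tag: str) -> dict:
    """Deterministic attributes of a planted causal variant."""
    code = _crc(f"{gene}|{tag}")
    chrom, start = gene_locus(gene)
    pos = start + code % 90_000
    ref = _BASES[code % 4]
    alt = _BASES[(code % 4 + 1 + (code >> 7) % 3) % 4]
    effect = ("nonsense", "missense", "frameshift", "splice")[(code >> 3) % 4]
    annotated = code % 3 != 0
    return {
        "variant_id": f"{gene}:{pos}:{ref}>{alt}",
        "chromosome": chrom,
        "position": pos,
        "ref": ref,
        "alt": alt,
        "effect": effect,
        "population_af": (code % 50) / 10_000 if annotated else None,
        "inhouse_af": (code % 40) / 1_000,
        "n_damaging": 3 if effect == "missense" else (code >> 9) % 5,
        "acmg_class": 5 if code % 2 else 4,
    }


def _assign(genotypes: FamilyGenotypes, vid: str, member_gts: dict[str, str]) -> None:
    genotypes.setdefault(vid, {}).update(member_gts)


def _causal_genotypes(family: FamilySpec, mode: str, vid: str, which: int = 0) -> dict[str, str]:
    """Mendelian-consistent genotypes for one causal variant under a mode."""
    gts: dict[str, str] = {}
    affected = family.affected
    father = affected[0].father_id
    mother = affected[0].mother_id
    if mode == "AR_hom":
        for m in affected:
            gts[m.member_id] = "hom_alt"
        if father:
            gts[father] = "het"
        if mother:
            gts[mother] = "het"
    elif mode == "AR_comphet":
        for m in affected:
            gts[m.member_id] = "het"
        if father:
            gts[father] = "het" if which == 0 else "hom_ref"
        if mother:
            gts[mother] = "hom_ref" if which == 0 else "het"
    elif mode == "XLR":
        for m in affected:
            gts[m.member_id] = "hemi" if m.sex == "m" else "hom_alt"
        if father:
            gts[father] = "hom_ref"
        if mother:
            gts[mother] = "het"
    elif mode in ("XLD_denovo", "AD_denovo"):
        for m in affected:
            gts[m.member_id] = "het"
        if father:
            gts[father] = "hom_ref"
        if mother:
            gts[mother] = "hom_ref"
    elif mode == "AD_inherited":
        for m in affected:
            gts[m.member_id] = "het"
        if father:
            gts[father] = "het"  # transmitting parent; flagged subclinical in the manifest
        if mother:
            gts[mother] = "hom_ref"
    elif mode == "AD_unknown":
        for m in affected:
            gts[m.member_id] = "het"
        # parents unavailable: no parental genotypes
    else:
        raise ValueError(f"unknown planted mode {mode!r}")
    return gts


def generate_wes_variants(
    family: FamilySpec, cfg: SimulationConfig
) -> tuple[list[NuclearVariant], FamilyGenotypes, dict]:
    """Annotated exome variant table plus per-member genotypes.

    Causal variants satisfy the rarity/effect/segregation conditions of
    their planted mode; background variants are engineered to fall out of
    the cascade and carry class <=3 annotations.
    """
    planted = family.planted
    if planted is not None and not planted.category.startswith("nuclear"):
        # mtDNA families carry no nuclear plant; exome is background-only
        planted = None
    rng = family_rng(family.family_id, cfg.seed, "wes")
    variants: list[NuclearVariant] = []
    genotypes: FamilyGenotypes = {}
    truth: dict = {"family_id": family.family_id, "causal": []}

    if planted is not None:
        for pg in planted.genes:
            if pg.mode == "XLR" and not any(m.sex == "m" for m in family.affected):
                raise ValueError(
                    f"{family.family_id}: XLR defect requires an affected male"
                )
            if pg.mode in ("XLD_denovo", "AD_denovo") and not family.parents_available:
                raise ValueError(
                    f"{family.family_id}: de novo status requires parental genotypes"
                )
            n_vars = 2 if pg.mode == "AR_comphet" else 1
            for k in range(n_vars):
                attrs = _hash_variant(pg.gene, f"causal{k}")
                v = NuclearVariant(
                    gene=pg.gene,
                    mitocarta=pg.mitocarta,
                    omim_dominant=pg.mode in ("AD_denovo", "AD_inherited", "AD_unknown", "XLD_denovo"),
                    **attrs,
                )
                variants.append(v)
                _assign(genotypes, v.variant_id, _causal_genotypes(family, pg.mode, v.variant_id, k))
                truth["causal"].append({"gene": pg.gene, "mode": pg.mode, "variant_id": v.variant_id})

    variants.extend(_background_variants(family, cfg, rng, genotypes))
    order = rng.permutation(len(variants))
    variants = [variants[i] for i in order]
    return variants, genotypes, truth


_BG_KINDS = (
    "common",
    "common",
    "benign_missense",
    "synonymous",
    "rare_het_nonpanel",
    "inhouse_common",
    "cis_pair",
    "hom_in_parent",
)


def _background_variants(family, cfg, rng, genotypes) -> list[NuclearVariant]:
    out: list[NuclearVariant] = []
    affected = family.affected
    father = affected[0].father_id
    mother = affected[0].mother_id
    counter = 0
    while len(out) < cfg.background_variants_per_exome:
        kind = _BG_KINDS[int(rng.integers(0, len(_BG_KINDS)))]
        counter += 1
        gene = f"BG{_crc(family.family_id) % 1000:03d}_{counter:04d}"
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(5_000_000, 140_000_000))
        ref_i = int(rng.integers(0, 4))
        ref = _BASES[ref_i]
        alt = _BASES[(ref_i + 1 + int(rng.integers(0, 3))) % 4]
        common = dict(
            gene=gene, chromosome=chrom, ref=ref, alt=alt,
            acmg_class=int(rng.integers(1, 4)), mitocarta=False, omim_dominant=False,
        )

        def mk(vid_pos, effect, pop_af, ih_af, n_dmg, suffix=""):
            return NuclearVariant(
                variant_id=f"{gene}{suffix}:{vid_pos}:{ref}>{alt}",
                position=vid_pos, effect=effect,
                population_af=pop_af, inhouse_af=ih_af, n_damaging=n_dmg,
                **common,
            )

        inherited = "het_father" if rng.integers(0, 2) else "het_mother"

        def plant(v, pattern):
            out.append(v)
            gts = {}
            for m in affected:
                gts[m.member_id] = pattern["affected"]
            if father:
                gts[father] = pattern["father"]
            if mother:
                gts[mother] = pattern["mother"]
            _assign(genotypes, v.variant_id, gts)

        het_from = {
            "affected": "het",
            "father": "het" if inherited == "het_father" else "hom_ref",
            "mother": "het" if inherited == "het_mother" else "hom_ref",
        }
        if kind == "common":
            v = mk(pos, "missense", float(rng.uniform(0.02, 0.4)), float(rng.uniform(0.02, 0.4)),
                   int(rng.integers(0, 5)))
            plant(v, het_from)
        elif kind == "benign_missense":
            v = mk(pos, "missense", float(rng.uniform(0, 0.005)), float(rng.uniform(0, 0.01)), 0)
            plant(v, het_from)
        elif kind == "synonymous":
            v = mk(pos, "synonymous", float(rng.uniform(0, 0.005)), float(rng.uniform(0, 0.01)),
                   int(rng.integers(0, 5)))
            plant(v, het_from)
        elif kind == "rare_het_nonpanel":
            v = mk(pos, "nonsense", float(rng.uniform(0, 0.005)), float(rng.uniform(0, 0.01)), 4)
            plant(v, het_from)
        elif kind == "inhouse_common":
            v = mk(pos, "frameshift", None, float(rng.uniform(0.06, 0.3)), 4)
            plant(v, het_from)
        elif kind == "cis_pair":
            v1 = mk(pos, "nonsense", float(rng.uniform(0, 0.005)), 0.0, 4)
            v2 = mk(pos + 500, "missense", None, float(rng.uniform(0, 0.01)), 3)
            cis = {"affected": "het", "father": "hom_ref", "mother": "het"}
            plant(v1, cis)
            plant(v2, cis)
        elif kind == "hom_in_parent":
            v = mk(pos, "missense", float(rng.uniform(0, 0.005)), float(rng.uniform(0, 0.01)), 3)
            plant(v, {"affected": "hom_alt", "father": "hom_alt", "mother": "het"})
    return out[: cfg.background_variants_per_exome]


# ---------------------------------------------------------------------------
# genotype tracks for homozygosity mapping

_MARKER_SPACING = 50_000
_TRACK_SPAN = 30_000_000
_CAUSAL_RUN = (12_000_000, 18_500_000)  # 6.5 Mb embedded run (track coordinates)
_SHORT_RUN = (22_000_000, 25_000_000)  # 3 Mb: below the 5 Mb cutoff
_DECOY_CHROM_RUN = (8_000_000, 12_900_000)  # 4.9 Mb decoy on a second chromosome


def generate_genotype_track(
    family: FamilySpec, cfg: SimulationConfig
) -> dict[str, list[tuple[str, int, str]]]:
    """Per-affected-member SNP genotype tracks.

    Consanguineous families carry one homozygous run >= 5 Mb containing
    their planted homozygous variant (when one exists) plus sub-cutoff
    decoy runs; non-consanguineous families carry only sub-cutoff runs.
    Outside designated runs markers are heterozygous (occasionally
    missing, which never breaks a run), so a designated run is detected
    at exactly its marker span and no spurious run can reach the cutoff.
    """
    rng = family_rng(family.family_id, cfg.seed, "track")
    chrom, anchor_pos = _track_anchor(family)
    offset = anchor_pos - (_CAUSAL_RUN[0] + _CAUSAL_RUN[1]) // 2 if anchor_pos else 0
    offset = max(offset, -11_000_000)  # keep track coordinates positive

    runs: list[tuple[int, int]] = []
    if family.consanguineous:
        runs.append((_CAUSAL_RUN[0] + offset, _CAUSAL_RUN[1] + offset))
    runs.append((_SHORT_RUN[0] + offset, _SHORT_RUN[1] + offset))

    tracks: dict[str, list[tuple[str, int, str]]] = {}
    for m in family.affected:
        rows: list[tuple[str, int, str]] = []
        for i in range(_TRACK_SPAN // _MARKER_SPACING):
            pos = offset + 1_000_000 + i * _MARKER_SPACING
            if pos < 1:
                continue
            if any(lo <= pos <= hi for lo, hi in runs):
                gt = "hom_alt" if rng.random() < 0.5 else "hom_ref"
            else:
                gt = "het" if rng.random() < 0.8 else "missing"
            rows.append((chrom, pos, gt))
        # decoy chromosome with a 4.9 Mb run (never reaches the cutoff)
        decoy_chrom = "20" if chrom != "20" else "21"
        for i in range(16_000_000 // _MARKER_SPACING):
            pos = 1_000_000 + i * _MARKER_SPACING
            lo, hi = _DECOY_CHROM_RUN
            if lo <= pos <= hi:
                gt = "hom_alt" if rng.random() < 0.5 else "hom_ref"
            else:
                gt = "het"
            rows.append((decoy_chrom, pos, gt))
        tracks[m.member_id] = rows
    return tracks


def _track_anchor(family: FamilySpec) -> tuple[str, int | None]:
    """Chromosome (and causal position, if any) the main track covers."""
    planted = family.planted
    if planted is not None and planted.category.startswith("nuclear"):
        for pg in planted.genes:
            if pg.mode == "AR_hom":
                attrs = _hash_variant(pg.gene, "causal0")
                return attrs["chromosome"], attrs["position"]
    return "5", None


# ---------------------------------------------------------------------------
# bundle


@dataclass
class FamilyInputs:
    family: FamilySpec
    reads: list[MtRead]
    pileups: list[MtPileup]
    qpcr_ratio: float
    control_ratios: list[float]
    variants: list[NuclearVariant]
    genotypes: FamilyGenotypes
    tracks: dict[str, list[tuple[str, int, str]]]
    truth: dict = field(default_factory=dict)


def generate_family_inputs(family: FamilySpec, cfg: SimulationConfig) -> FamilyInputs:
    """All synthetic inputs for one family under one configuration."""
    reads, pileups, mt_truth = generate_mt_reads(family, cfg)
    ratio, controls, qpcr_truth = generate_qpcr(family, cfg)
    variants, genotypes, wes_truth = generate_wes_variants(family, cfg)
    tracks = generate_genotype_track(family, cfg)
    return FamilyInputs(
        family=family,
        reads=reads,
        pileups=pileups,
        qpcr_ratio=ratio,
        control_ratios=controls,
        variants=variants,
        genotypes=genotypes,
        tracks=tracks,
        truth={"mt": mt_truth, "qpcr": qpcr_truth, "wes": wes_truth},
    )
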