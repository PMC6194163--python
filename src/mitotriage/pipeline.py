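"""Two-step cohort pipeline and diagnostic-yield reporting.

Every family is screened at the mtDNA stage first (point variants,
large-deletion breakpoints, copy number); a solving mtDNA finding stops
the workup, while a negative result — or an escalating one (multiple
deletions, depletion) — sends the family to exome analysis under the
inheritance-model strategy its structure dictates.  The cohort report
aggregates per-family outcomes into the yield fractions that summarise a
diagnostic study: stage and overall yields, strategy- and group-wise
exome yields, the de novo fraction, the mtDNA mutation spectrum and the
fraction of causal genes missed by a mitochondrial gene panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .cohort import CohortManifest, FamilySpec, mitocarta_panel, omim_dominant_panel
from .mtdna import (
    assess_copy_number,
    call_point_variants,
    classify_mt_findings,
    detect_deletions,
)
from .refseq import load_known_pathogenic, mt_reference
from .roh import detect_roh
from .simulate import FamilyInputs, SimulationConfig, generate_family_inputs
from .wes import (
    DiagnosisResult,
    diagnose_family,
    dominant_candidates,
    filter_cascade,
    recessive_candidates,
)


def pct(numerator: int, denominator: int) -> int | None:
    """Whole-percent rounding, half away from zero (display convention)."""
    if denominator == 0:
        return None
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class Fraction:
    numerator: int
    denominator: int

    @property
    def percent(self) -> int | None:
        return pct(self.numerator, self.denominator)

    @property
    def undefined(self) -> bool:
        return self.denominator == 0

    def as_dict(self) -> dict:
        return {"n": self.numerator, "d": self.denominator, "percent": self.percent}

    def __str__(self) -> str:
        if self.undefined:
            return "undefined (0 denominator)"
        return f"{self.percent}% ({self.numerator}/{self.denominator})"


@dataclass
class CohortReport:
    results: list[DiagnosisResult]
    manifest: CohortManifest
    errored: list[str] = field(default_factory=list)

    def _by_id(self) -> dict[str, FamilySpec]:
        return {f.family_id: f for f in self.manifest}

    # --- stage yields -----------------------------------------------------
    @property
    def total(self) -> int:
        return len(self.results)

    @property
    def mt_solved(self) -> list[DiagnosisResult]:
        return [r for r in self.results if r.solved and r.stage == "mtDNA"]

    @property
    def wes_solved(self) -> list[DiagnosisResult]:
        return [r for r in self.results if r.solved and r.stage == "WES"]

    @property
    def overall_yield(self) -> Fraction:
        return Fraction(len(self.mt_solved) + len(self.wes_solved), self.total)

    @property
    def mt_yield(self) -> Fraction:
        return Fraction(len(self.mt_solved), self.total)

    @property
    def wes_yield(self) -> Fraction:
        return Fraction(len(self.wes_solved), self.total)

    # --- strategy/group breakdowns ---------------------------------------
    def wes_entered(self, strategy: str | None = None, group: int | None = None):
        """Families that entered the exome stage (not solved at the mtDNA
        stage), optionally restricted by strategy and group."""
        fams = self._by_id()
        out = []
        for r in self.results:
            if r.stage != "WES":
                continue
            fam = fams[r.family_id]
            if strategy and fam.strategy != strategy:
                continue
            if group and fam.group != group:
                continue
            out.append(r)
        return out

    def wes_strategy_yield(self, strategy: str, group: int | None = None) -> Fraction:
        entered = self.wes_entered(strategy, group)
        return Fraction(sum(1 for r in entered if r.solved), len(entered))

    @property
    def de_novo_fraction(self) -> Fraction:
        entered = self.wes_entered("B")
        return Fraction(sum(1 for r in entered if r.solved and r.de_novo), len(entered))

    # --- mtDNA spectrum ---------------------------------------------------
    def mtdna_breakdown(self) -> dict:
        """Counts per mutation identity and deletion event among the
        mtDNA-stage diagnoses."""
        solved = self.mt_solved
        by_allele: dict[str, int] = {}
        by_label: dict[str, int] = {}
        deletions: dict[str, int] = {}
        for r in solved:
            if r.mt_deletion is not None:
                b5, b3 = r.mt_deletion
                key = f"{b5}:{b3}"
                deletions[key] = deletions.get(key, 0) + 1
            elif r.mt_variant:
                by_allele[r.mt_variant] = by_allele.get(r.mt_variant, 0) + 1
                if r.mt_label:
                    by_label[r.mt_label] = by_label.get(r.mt_label, 0) + 1
        n = len(solved)
        return {
            "n_mt_solved": n,
            "by_allele": by_allele,
            "by_syndrome": by_label,
            "single_deletions": deletions,
            "lhon_fraction": Fraction(by_label.get("LHON", 0), n),
            "m3243_fraction": Fraction(by_allele.get("m.3243A>G", 0), n),
            "deletion_fraction": Fraction(sum(deletions.values()), n),
        }

    def mitocarta_summary(self, group: int = 1) -> Fraction:
        """Fraction of causal genes in group-``group`` exome diagnoses that
        are absent from the mitochondrial gene panel; multi-genic families
        contribute every causal gene."""
        fams = self._by_id()
        absent = total = 0
        for r in self.wes_solved:
            if fams[r.family_id].group != group:
                continue
            total += len(r.genes)
            absent += sum(1 for flag in r.mitocarta_flags if not flag)
        return Fraction(absent, total)

    # --- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        breakdown = self.mtdna_breakdown()
        return {
            "n_families": self.total,
            "overall_yield": self.overall_yield.as_dict(),
            "mt_yield": self.mt_yield.as_dict(),
            "wes_yield": self.wes_yield.as_dict(),
            "wes_strategy_A": self.wes_strategy_yield("A").as_dict(),
            "wes_strategy_B": self.wes_strategy_yield("B").as_dict(),
            "wes_strategy_A_group1": self.wes_strategy_yield("A", 1).as_dict(),
            "wes_strategy_A_group2": self.wes_strategy_yield("A", 2).as_dict(),
            "wes_strategy_B_group1": self.wes_strategy_yield("B", 1).as_dict(),
            "wes_strategy_B_group2": self.wes_strategy_yield("B", 2).as_dict(),
            "de_novo_fraction": self.de_novo_fraction.as_dict(),
            "mitocarta_absent_group1": self.mitocarta_summary(1).as_dict(),
            "mtdna_breakdown": {
                "by_allele": breakdown["by_allele"],
                "by_syndrome": breakdown["by_syndrome"],
                "single_deletions": breakdown["single_deletions"],
                "lhon_fraction": breakdown["lhon_fraction"].as_dict(),
                "m3243_fraction": breakdown["m3243_fraction"].as_dict(),
                "deletion_fraction": breakdown["deletion_fraction"].as_dict(),
            },
            "errored_families": list(self.errored),
        }

    def results_table(self):
        """Per-family outcome table as a pandas DataFrame."""
        import pandas as pd

        fams = self._by_id()
        rows = []
        for r in self.results:
            fam = fams[r.family_id]
            rows.append(
                {
                    "family_id": r.family_id,
                    "strategy": fam.strategy,
                    "group": fam.group,
                    "stage": r.stage,
                    "solved": r.solved,
                    "genes": ";".join(r.genes),
                    "modes": ";".join(r.modes),
                    "mt_variant": r.mt_variant,
                    "mt_deletion": f"{r.mt_deletion[0]}:{r.mt_deletion[1]}" if r.mt_deletion else "",
                    "de_novo": r.de_novo,
                    "multi_genic": r.multi_genic,
                }
            )
        return pd.DataFrame(rows)


def run_family(
    family: FamilySpec,
    cfg: SimulationConfig,
    known_table,
    mitocarta,
    omim_ad,
    reference: str,
    inputs: FamilyInputs | None = None,
) -> DiagnosisResult:
    """Run the two-step strategy for one family."""
    if inputs is None:
        inputs = generate_family_inputs(family, cfg)

    calls = call_point_variants(inputs.pileups, known_table)
    has_junction = any(r.aligned_pos is None for r in inputs.reads)
    deletions = detect_deletions(inputs.reads, reference) if has_junction else []
    copy_number = assess_copy_number(inputs.qpcr_ratio, inputs.control_ratios)
    mt_dx = classify_mt_findings(calls, deletions, copy_number)

    if mt_dx.outcome == "solved_point":
        call = next(c for c in mt_dx.point_calls if c.known_pathogenic and c.passed_cutoff)
        return DiagnosisResult(
            family_id=family.family_id,
            solved=True,
            stage="mtDNA",
            mt_outcome=mt_dx.outcome,
            mt_variant=f"m.{call.position}{call.ref}>{call.alt}",
            mt_label=call.label,
        )
    if mt_dx.outcome == "solved_single_deletion":
        d = mt_dx.deletions[0]
        return DiagnosisResult(
            family_id=family.family_id,
            solved=True,
            stage="mtDNA",
            mt_outcome=mt_dx.outcome,
            mt_deletion=(d.b5, d.b3),
        )

    # exome stage
    kept = filter_cascade(inputs.variants)
    roh = []
    for member_id, track in inputs.tracks.items():
        roh.extend(detect_roh(track, member_id=member_id))
    candidates = recessive_candidates(family, kept, inputs.genotypes, roh)
    if family.strategy == "B":
        candidates += dominant_candidates(family, kept, inputs.genotypes, omim_ad)
    result = diagnose_family(family, candidates, inputs.genotypes, mitocarta)
    return replace(result, mt_outcome=mt_dx.outcome)


def run_pipeline(
    manifest: CohortManifest,
    cfg: SimulationConfig | None = None,
    mitocarta: frozenset[str] | None = None,
    omim_ad: frozenset[str] | None = None,
    strict: bool = False,
) -> CohortReport:
    """Run the full two-step strategy over a cohort manifest.

    A per-family failure is flagged and excluded from denominators with a
    warning unless ``strict`` aborts the run.
    """
    cfg = cfg or SimulationConfig()
    mitocarta = mitocarta if mitocarta is not None else mitocarta_panel()
    omim_ad = omim_ad if omim_ad is not None else omim_dominant_panel()
    known_table = load_known_pathogenic()
    reference = mt_reference()

    results: list[DiagnosisResult] = []
    errored: list[str] = []
    for family in manifest:
        try:
            results.append(
                run_family(family, cfg, known_table, mitocarta, omim_ad, reference)
            )
        except Exception:
            if strict:
                raise
            warnings.warn(
                f"family {family.family_id} errored; excluded from denominators",
                stacklevel=2,
            )
            errored.append(family.family_id)
    return CohortReport(results=results, manifest=manifest, errored=errored)
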