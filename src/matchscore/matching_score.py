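"""Matching Score engine.

The Matching Score quantifies, on a 0-100% scale, how completely an
administered drug regimen targets a tumour's deleterious molecular
alterations.  At its core it is the fraction

    score = 100 * (alterations targeted by the regimen) / (all counted alterations)

with the following refinements:

* a synergistic two-drug combination acting on one alteration (both
  partners given) counts that alteration twice in numerator and
  denominator;
* ER/AR IHC positivity targeted by a hormone modulator adds one to both
  numerator and denominator;
* checkpoint blockade is scored through immune biomarkers rather than
  the alteration fraction: MSI-high, TMB >= 20 mut/Mb, or high PD-L1
  yields 100%; TMB-intermediate or low-positive PD-L1 yields 50%, to
  which half of the targeted fraction of the remaining (non-immune)
  alterations is added: score = 50 + 100*n/(2d);
* no score exceeds 100%.

Scores are computed as exact rationals and reported to one decimal, so
the >50% dichotomisation boundary is never subject to float error.
Every counted unit is recorded in an audit ledger with the rule that
fired and the drugs that matched it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .knowledge_base import (
    DrugClass,
    DrugEntry,
    KnowledgeBase,
    effective_target_genes,
)
from .patient_model import (
    CountableUnit,
    IHCStatus,
    ImmuneBiomarkers,
    MSIStatus,
    PatientProfile,
    PDL1Category,
    TMBCategory,
    classify_pdl1,
    classify_tmb,
    pool_countable_alterations,
)

__all__ = [
    "CheckpointComponent",
    "LedgerEntry",
    "MatchingScoreResult",
    "checkpoint_component",
    "targeted_fraction",
    "compute_matching_score",
    "dichotomize_score",
]


class CheckpointComponent(str, Enum):
    ABSENT = "absent"   # no checkpoint inhibitor in the regimen
    ZERO = "zero"       # checkpoint given, no qualifying immune biomarker
    HALF = "half"       # TMB-intermediate or low-positive PD-L1
    FULL = "full"       # MSI-high, TMB-high, or high PD-L1


@dataclass(frozen=True)
class LedgerEntry:
    """One audited counting event: a unit's contribution to the score."""

    label: str
    multiplicity: int          # contribution to the denominator
    matched: bool              # whether it also enters the numerator
    matched_by: tuple[str, ...]
    rule: str


@dataclass
class MatchingScoreResult:
    numerator: int
    denominator: int
    checkpoint_component: CheckpointComponent
    score: Fraction            # exact, in percent units
    ledger: list[LedgerEntry] = field(default_factory=list)

    @property
    def score_percent(self) -> float:
        """Score in percent, rounded to one decimal."""
        return round(float(self.score), 1)

    @property
    def matched(self) -> bool:
        return self.score > 0


def _split_regimen(
    regimen: Sequence[str], kb: KnowledgeBase
) -> tuple[list[DrugEntry], list[DrugEntry]]:
    entries = kb.resolve_regimen(regimen)
    checkpoint = [e for e in entries if e.drug_class is DrugClass.CHECKPOINT_INHIBITOR]
    other = [e for e in entries if e.drug_class is not DrugClass.CHECKPOINT_INHIBITOR]
    return checkpoint, other


def checkpoint_component(
    biomarkers: ImmuneBiomarkers,
    regimen: Sequence[str],
    kb: KnowledgeBase,
) -> CheckpointComponent:
    """Immune-biomarker score tier for checkpoint blockade in the regimen.

    ``full`` (100%) for MSI-high, TMB >= 20 mut/Mb, or high PD-L1;
    ``half`` (50%) for TMB-intermediate or low-positive PD-L1; ``zero``
    when checkpoint blockade was given without any qualifying biomarker;
    ``absent`` when the regimen contains no checkpoint inhibitor.
    """
    checkpoint, _ = _split_regimen(regimen, kb)
    if not checkpoint:
        return CheckpointComponent.ABSENT
    tmb_cat = (
        classify_tmb(biomarkers.tmb_mut_per_mb)
        if biomarkers.tmb_mut_per_mb is not None
        else None
    )
    pdl1_cat = (
        classify_pdl1(biomarkers.pdl1_percent)
        if biomarkers.pdl1_percent is not None
        else None
    )
    if (
        biomarkers.msi_status is MSIStatus.MSI_HIGH
        or tmb_cat is TMBCategory.HIGH
        or pdl1_cat is PDL1Category.HIGH
    ):
        return CheckpointComponent.FULL
    if tmb_cat is TMBCategory.INTERMEDIATE or pdl1_cat is PDL1Category.LOW_POSITIVE:
        return CheckpointComponent.HALF
    return CheckpointComponent.ZERO


def _synergy_genes_in_regimen(
    regimen_entries: Iterable[DrugEntry], kb: KnowledgeBase
) -> set[str]:
    """Genes whose synergy pair is complete within the regimen."""
    names = {e.name.lower() for e in regimen_entries}
    genes = set()
    for a, b, gene in kb.synergy_pairs:
        if a in names and b in names:
            genes.add(gene)
    return genes


def targeted_fraction(
    units: Sequence[CountableUnit],
    biomarkers: ImmuneBiomarkers,
    regimen: Sequence[str],
    kb: KnowledgeBase,
) -> tuple[int, int, list[LedgerEntry]]:
    """Numerator and denominator of the alteration-targeting fraction.

    A unit is matched when any non-checkpoint regimen drug's effective
    target set contains its gene.  Matched units covered by a complete
    synergy pair in the regimen count twice on both sides; hormone
    receptor positivity (ER/AR) targeted by a hormone modulator adds one
    matched unit.  Checkpoint inhibitors contribute nothing here.
    """
    _, drugs = _split_regimen(regimen, kb)
    targets = {d.name: effective_target_genes(d, kb) for d in drugs}
    synergy_genes = _synergy_genes_in_regimen(drugs, kb)

    ledger: list[LedgerEntry] = []
    numerator = denominator = 0
    for unit in units:
        matched_by = tuple(
            sorted(name for name, genes in targets.items() if unit.label in genes)
        )
        mult = unit.multiplicity
        rule = unit.rationale
        if matched_by and unit.label in synergy_genes:
            mult *= 2
            rule += "; synergy pair doubled"
        denominator += mult
        if matched_by:
            numerator += mult
        ledger.append(
            LedgerEntry(
                label=unit.label,
                multiplicity=mult,
                matched=bool(matched_by),
                matched_by=matched_by,
                rule=rule,
            )
        )

    hormone_mods = [d for d in drugs if d.drug_class is DrugClass.HORMONE_MODULATOR]
    for marker, status in (("ER", biomarkers.er_ihc), ("AR", biomarkers.ar_ihc)):
        if status is not IHCStatus.POSITIVE:
            continue
        matched_by = tuple(
            sorted(d.name for d in hormone_mods if marker in targets[d.name])
        )
        if matched_by:
            numerator += 1
            denominator += 1
            ledger.append(
                LedgerEntry(
                    label=marker,
                    multiplicity=1,
                    matched=True,
                    matched_by=matched_by,
                    rule=f"{marker}+ IHC targeted by hormone modulator",
                )
            )
    return numerator, denominator, ledger


def compute_matching_score(
    profile: PatientProfile,
    regimen: Sequence[str],
    kb: KnowledgeBase,
    *,
    dedup_across_assays: bool = False,
    pathway_map: Optional[dict[str, str]] = None,
) -> MatchingScoreResult:
    """Score one patient's regimen against their molecular profile.

    Returns an auditable result; ``score`` is exact (a Fraction in
    percent units), capped at 100.
    """
    if not regimen:
        raise ValueError("regimen must contain at least one drug")
    units = pool_countable_alterations(
        profile.assay_results,
        dedup_across_assays=dedup_across_assays,
        pathway_map=pathway_map,
    )
    cc = checkpoint_component(profile.biomarkers, regimen, kb)
    n, d, ledger = targeted_fraction(units, profile.biomarkers, regimen, kb)

    if cc is CheckpointComponent.FULL:
        score = Fraction(100)
    elif cc is CheckpointComponent.HALF:
        extra = Fraction(100 * n, 2 * d) if d else Fraction(0)
        score = Fraction(50) + extra
    else:
        score = Fraction(100 * n, d) if d else Fraction(0)
    score = min(score, Fraction(100))

    return MatchingScoreResult(
        numerator=n,
        denominator=d,
        checkpoint_component=cc,
        score=score,
        ledger=ledger,
    )


def dichotomize_score(score_percent: float, cutoff: float = 50.0) -> str:
    """Assign ``"high"`` when score > cutoff (strict), else ``"low"``.

    Unmatched patients (score 0) always fall in the low group.
    """
    if not 0 <= score_percent <= 100:
        raise ValueError("score must lie in [0, 100]")
    return "high" if score_percent > cutoff else "low"
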