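"""Patient-level data model and deterministic preprocessing.

Holds deleterious genomic alterations from one or more assays (tissue
NGS and/or blood cfDNA), immune biomarkers, and treatment outcomes, and
implements the counting rules that turn raw assay reports into the
countable units of the Matching Score denominator:

* within one assay, alterations in the same gene of the same structural
  class (e.g. two point mutations in KRAS) count as one unit;
* structurally distinct alterations of the same gene (amplification and
  mutation) count separately;
* each assay result is counted on its own — tumour heterogeneity between
  tissue and blood means the same gene seen in two tests yields two
  units by default (a dedup toggle collapses them instead).

Variants of unknown significance are never stored: callers must filter
to deleterious calls before constructing :class:`Alteration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

__all__ = [
    "AlterationClass",
    "MSIStatus",
    "IHCStatus",
    "BestResponse",
    "TMBCategory",
    "PDL1Category",
    "RNALevel",
    "Alteration",
    "AssayResult",
    "ImmuneBiomarkers",
    "PatientProfile",
    "CountableUnit",
    "OutcomeRecord",
    "NotEvaluableError",
    "pool_countable_alterations",
    "classify_tmb",
    "classify_pdl1",
    "clinical_benefit",
]


class AlterationClass(str, Enum):
    MUTATION = "mutation"
    AMPLIFICATION = "amplification"
    DELETION = "deletion"
    FUSION = "fusion"
    REARRANGEMENT = "rearrangement"


class MSIStatus(str, Enum):
    MSI_HIGH = "msi_high"
    STABLE = "stable"
    UNKNOWN = "unknown"


class IHCStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class BestResponse(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NOT_EVALUABLE = "not_evaluable"


class TMBCategory(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


class PDL1Category(str, Enum):
    NEGATIVE = "negative"
    LOW_POSITIVE = "low_positive"
    HIGH = "high"


class RNALevel(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"
    VERY_HIGH = "very_high"


class NotEvaluableError(ValueError):
    """Best response not evaluable; exclude the patient from benefit analyses."""


@dataclass(frozen=True)
class Alteration:
    """One deleterious genomic alteration (never a VUS)."""

    gene: str
    alteration_class: AlterationClass
    assay_id: str
    descriptor: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("alteration gene symbol must be non-empty")


@dataclass
class AssayResult:
    assay_id: str
    assay_type: str  # "tissue_ngs" | "cfdna"
    alterations: list[Alteration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.assay_type not in ("tissue_ngs", "cfdna"):
            raise ValueError(f"unknown assay type {self.assay_type!r}")
        for alt in self.alterations:
            if alt.assay_id != self.assay_id:
                raise ValueError(
                    f"alteration {alt.gene} carries assay_id {alt.assay_id!r}, "
                    f"expected {self.assay_id!r}"
                )


@dataclass
class ImmuneBiomarkers:
    tmb_mut_per_mb: Optional[float] = None
    msi_status: MSIStatus = MSIStatus.UNKNOWN
    pdl1_percent: Optional[float] = None
    er_ihc: IHCStatus = IHCStatus.UNKNOWN
    ar_ihc: IHCStatus = IHCStatus.UNKNOWN
    rna_immune_levels: Optional[dict[str, RNALevel]] = None

    def __post_init__(self) -> None:
        if self.tmb_mut_per_mb is not None and self.tmb_mut_per_mb < 0:
            raise ValueError("TMB must be non-negative")
        if self.pdl1_percent is not None and not 0 <= self.pdl1_percent <= 100:
            raise ValueError("PD-L1 percent must lie in [0, 100]")


@dataclass
class PatientProfile:
    patient_id: str
    assay_results: list[AssayResult] = field(default_factory=list)
    biomarkers: ImmuneBiomarkers = field(default_factory=ImmuneBiomarkers)


@dataclass(frozen=True)
class CountableUnit:
    """One counted alteration unit in the Matching Score denominator."""

    label: str
    multiplicity: int
    source_assay_ids: frozenset[str]
    rationale: str

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass
class OutcomeRecord:
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    best_response: BestResponse
    sd_duration_months: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be non-negative")
        if self.pfs_event and self.os_event and self.pfs_months > self.os_months:
            raise ValueError("observed progression cannot postdate observed death")


def pool_countable_alterations(
    assay_results: Iterable[AssayResult],
    *,
    dedup_across_assays: bool = False,
    pathway_map: Optional[Mapping[str, str]] = None,
) -> list[CountableUnit]:
    """Collapse raw alterations into countable units.

    Within each assay, alterations sharing label and class collapse to a
    single unit; the label is the gene symbol, or the pathway name when
    ``pathway_map`` assigns the gene to a pathway (so that two genes
    hitting the same pathway count once).  Units from different assays
    are kept separate unless ``dedup_across_assays`` is set.  Output
    order is deterministic: sorted by assay id, label, class.
    """
    per_assay: dict[tuple[str, str, str], set[str]] = {}
    for assay in assay_results:
        for alt in assay.alterations:
            if not alt.gene:
                raise ValueError("alteration gene symbol must be non-empty")
            label = pathway_map.get(alt.gene, alt.gene) if pathway_map else alt.gene
            key = (assay.assay_id, label, alt.alteration_class.value)
            per_assay.setdefault(key, set()).add(assay.assay_id)

    if dedup_across_assays:
        merged: dict[tuple[str, str], tuple[str, set[str]]] = {}
        for (assay_id, label, cls), sources in sorted(per_assay.items()):
            k = (label, cls)
            if k in merged:
                merged[k][1].update(sources)
            else:
                merged[k] = (assay_id, set(sources))
        return [
            CountableUnit(
                label=label,
                multiplicity=1,
                source_assay_ids=frozenset(sources),
                rationale=f"{cls} pooled across assays",
            )
            for (label, cls), (first_assay, sources) in sorted(
                merged.items(), key=lambda kv: (kv[1][0], kv[0])
            )
        ]

    return [
        CountableUnit(
            label=label,
            multiplicity=1,
            source_assay_ids=frozenset(sources),
            rationale=f"{cls} in assay {assay_id}",
        )
        for (assay_id, label, cls), sources in sorted(per_assay.items())
    ]


def classify_tmb(tmb_mut_per_mb: float) -> TMBCategory:
    """Bin tumour mutational burden: low <6, intermediate 6-19, high >=20 mut/Mb."""
    if tmb_mut_per_mb < 0:
        raise ValueError("TMB must be non-negative")
    if tmb_mut_per_mb < 6:
        return TMBCategory.LOW
    if tmb_mut_per_mb < 20:
        return TMBCategory.INTERMEDIATE
    return TMBCategory.HIGH


def classify_pdl1(
    pdl1_percent: float,
    low_threshold: float = 1.0,
    high_threshold: float = 50.0,
) -> PDL1Category:
    """Bin PD-L1 IHC staining percent: negative <1%, high >=50% (TPS convention)."""
    if not 0 <= pdl1_percent <= 100:
        raise ValueError("PD-L1 percent must lie in [0, 100]")
    if not 0 < low_threshold <= high_threshold:
        raise ValueError("thresholds must satisfy 0 < low <= high")
    if pdl1_percent < low_threshold:
        return PDL1Category.NEGATIVE
    if pdl1_percent < high_threshold:
        return PDL1Category.LOW_POSITIVE
    return PDL1Category.HIGH


def clinical_benefit(outcome: OutcomeRecord) -> bool:
    """Clinical benefit: CR/PR, or stable disease lasting >= 6 months."""
    if outcome.best_response is BestResponse.NOT_EVALUABLE:
        raise NotEvaluableError("best response not evaluable")
    if outcome.best_response in (BestResponse.CR, BestResponse.PR):
        return True
    if outcome.best_response is BestResponse.SD:
        if outcome.sd_duration_months is None:
            raise ValueError("stable disease requires sd_duration_months")
        return outcome.sd_duration_months >= 6
    return False
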