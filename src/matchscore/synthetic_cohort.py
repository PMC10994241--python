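"""Synthetic carcinoma-of-unknown-primary (CUP) cohort generator.

Emulates the molecular structure of a retrospectively profiled CUP
cohort so the whole scoring-and-analysis pipeline can be exercised with
no external data:

* each patient gets a tissue NGS and/or cfDNA assay; per-gene presence
  is drawn as independent Bernoulli trials with published marginal
  alteration frequencies (tissue TP53 55.4%, CDKN2A 24.3%, KRAS 20.3%;
  cfDNA TP53 61.1%, KRAS 20.8%, PIK3CA 16.7%), the remaining tail of the
  frequency table sized so the alteration count per assay has median 4
  (tissue, range capped at 25) and 2 (cfDNA, capped at 9);
* immune biomarkers are drawn from the published testing and positivity
  rates (TMB categories 62.5/28.1/9.4%, MSI-high 3.6%, PD-L1+ 30.9%);
* regimens follow a policy (matched-rich, random, or unmatched) over the
  default knowledge base; the Matching Score engine then scores them;
* outcomes are drawn from an exponential PFS/OS model in which the
  high-score group (score > 50%) has the better generating medians
  (10.4 vs 2.8 months PFS, 15.8 vs 6.9 OS) and a higher clinical-benefit
  probability (0.71 vs 0.24), with administrative censoring applied at a
  common follow-up time so recorded OS never precedes recorded PFS.

Gene co-occurrence is modelled as independent draws; there is no
mutual-exclusivity or clonal structure.  All randomness flows from the
single seed in :class:`SimulationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .knowledge_base import DrugClass, KnowledgeBase, default_kb, effective_target_genes
from .matching_score import compute_matching_score, dichotomize_score
from .patient_model import (
    Alteration,
    AlterationClass,
    AssayResult,
    BestResponse,
    IHCStatus,
    ImmuneBiomarkers,
    MSIStatus,
    OutcomeRecord,
    PatientProfile,
)

__all__ = [
    "OutcomeModel",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_outcomes",
    "TISSUE_GENE_FREQS",
    "CFDNA_GENE_FREQS",
]

# Marginal per-patient alteration frequencies.  The three head genes of
# each table carry published values; the tail is an illustrative
# long-tail of recurrently altered cancer genes sized so the exact
# Poisson-binomial median of the per-assay alteration count is 4
# (tissue) and 2 (cfDNA).
TISSUE_GENE_FREQS: dict[str, float] = {
    "TP53": 0.554, "CDKN2A": 0.243, "KRAS": 0.203,
    "PIK3CA": 0.21, "MYC": 0.18, "ARID1A": 0.165, "CCND1": 0.135,
    "PTEN": 0.12, "MCL1": 0.12, "SMAD4": 0.105, "BRAF": 0.105, "ERBB2": 0.105,
    "FGFR1": 0.09, "CCNE1": 0.09, "RB1": 0.09, "EGFR": 0.09,
    "STK11": 0.075, "NF1": 0.075, "BRCA2": 0.075, "KMT2D": 0.075, "APC": 0.075,
    "ATM": 0.075, "CTNNB1": 0.075, "GNAS": 0.06, "KIT": 0.06, "MET": 0.06,
    "NRAS": 0.06, "CDK4": 0.06, "FGFR2": 0.06, "MDM2": 0.06,
    "ARID2": 0.045, "BRCA1": 0.045, "PALB2": 0.045, "NOTCH1": 0.045,
    "KDM6A": 0.045, "TERT": 0.045, "AKT1": 0.045, "ESR1": 0.03,
    "ALK": 0.03, "ROS1": 0.03, "IDH1": 0.03, "FBXW7": 0.03,
    "MTOR": 0.03, "SF3B1": 0.03, "VHL": 0.03, "JAK2": 0.03,
    "SMARCA4": 0.03, "NFE2L2": 0.03, "TSC1": 0.03, "PDGFRA": 0.03,
}
CFDNA_GENE_FREQS: dict[str, float] = {
    "TP53": 0.611, "KRAS": 0.208, "PIK3CA": 0.167,
    "EGFR": 0.10, "MYC": 0.09, "BRAF": 0.08, "APC": 0.08,
    "CCND1": 0.07, "ERBB2": 0.07, "CDKN2A": 0.06, "ARID1A": 0.05,
    "PTEN": 0.05, "ATM": 0.05, "MET": 0.04, "FGFR1": 0.04,
    "BRCA2": 0.04, "CTNNB1": 0.04, "SMAD4": 0.04, "GNAS": 0.04,
    "NRAS": 0.04, "NF1": 0.03, "BRCA1": 0.03, "KIT": 0.03,
    "TERT": 0.03, "ALK": 0.02, "RB1": 0.02, "ESR1": 0.02,
    "STK11": 0.02, "AKT1": 0.02, "IDH1": 0.02,
}

# Alteration class assigned per gene (everything else is a mutation).
_AMPLIFIED = {"MYC", "CCND1", "CCNE1", "ERBB2", "FGFR1", "FGFR2", "EGFR",
              "MET", "CDK4", "MDM2", "MCL1", "AKT1"}
_DELETED = {"CDKN2A", "PTEN", "RB1", "SMAD4"}


def _alteration_class(gene: str) -> AlterationClass:
    if gene in _AMPLIFIED:
        return AlterationClass.AMPLIFICATION
    if gene in _DELETED:
        return AlterationClass.DELETION
    return AlterationClass.MUTATION


@dataclass(frozen=True)
class OutcomeModel:
    """Generating outcome distributions per Matching Score group."""

    pfs_median_high: float = 10.4
    pfs_median_low: float = 2.8
    os_median_high: float = 15.8
    os_median_low: float = 6.9
    benefit_prob_high: float = 0.71
    benefit_prob_low: float = 0.24
    censoring_fraction: float = 0.2

    def __post_init__(self) -> None:
        for m in (self.pfs_median_high, self.pfs_median_low,
                  self.os_median_high, self.os_median_low):
            if m <= 0:
                raise ValueError("medians must be positive")
        for p in (self.benefit_prob_high, self.benefit_prob_low,
                  self.censoring_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimulationConfig:
    n_patients: int = 200
    seed: int = 0
    tissue_gene_freqs: dict[str, float] = field(
        default_factory=lambda: dict(TISSUE_GENE_FREQS))
    cfdna_gene_freqs: dict[str, float] = field(
        default_factory=lambda: dict(CFDNA_GENE_FREQS))
    tissue_max_alterations: int = 25
    cfdna_max_alterations: int = 9
    p_tissue_assay: float = 0.76
    p_cfdna_assay: float = 0.74
    tmb_tested_prob: float = 64 / 97
    msi_tested_prob: float = 55 / 97
    pdl1_tested_prob: float = 55 / 97
    tmb_category_probs: tuple[float, float, float] = (0.625, 0.281, 0.094)
    msi_high_prob: float = 0.036
    pdl1_positive_prob: float = 0.309
    pdl1_high_given_positive: float = 0.3
    er_positive_prob: float = 0.12
    ar_positive_prob: float = 0.06
    regimen_policy: str = "matched_rich"   # matched_rich | random | unmatched
    cutoff: float = 50.0
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)

    def __post_init__(self) -> None:
        for table in (self.tissue_gene_freqs, self.cfdna_gene_freqs):
            for gene, p in table.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"gene frequency for {gene!r} outside [0, 1]")
        if self.regimen_policy not in ("matched_rich", "random", "unmatched"):
            raise ValueError(f"unknown regimen policy {self.regimen_policy!r}")
        if abs(sum(self.tmb_category_probs) - 1) > 1e-9:
            raise ValueError("TMB category probabilities must sum to 1")


@dataclass
class SimulatedCohort:
    profiles: list[PatientProfile]
    regimens: dict[str, list[str]]
    scores: dict[str, float]
    groups: dict[str, str]
    outcomes: dict[str, OutcomeRecord]
    demographics: pd.DataFrame  # patient_id, age, sex, histology

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """CSV-schema tables: patients, alterations, biomarkers,
        treatments, outcomes, scores."""
        alt_rows, bm_rows, trt_rows, out_rows, score_rows = [], [], [], [], []
        for p in self.profiles:
            for assay in p.assay_results:
                for alt in assay.alterations:
                    alt_rows.append(dict(
                        patient_id=p.patient_id, assay_id=alt.assay_id,
                        assay_type=assay.assay_type, gene=alt.gene,
                        alteration_class=alt.alteration_class.value,
                        descriptor=alt.descriptor or "",
                    ))
            bm = p.biomarkers
            bm_rows.append(dict(
                patient_id=p.patient_id,
                tmb_mut_per_mb="" if bm.tmb_mut_per_mb is None
                               else round(bm.tmb_mut_per_mb, 2),
                msi_status=bm.msi_status.value,
                pdl1_percent="" if bm.pdl1_percent is None
                             else round(bm.pdl1_percent, 2),
                er_ihc=bm.er_ihc.value, ar_ihc=bm.ar_ihc.value,
            ))
            trt_rows.append(dict(
                patient_id=p.patient_id, line=1,
                drugs=";".join(self.regimens[p.patient_id]),
            ))
            o = self.outcomes[p.patient_id]
            out_rows.append(dict(
                patient_id=p.patient_id,
                pfs_months=round(o.pfs_months, 4), pfs_event=int(o.pfs_event),
                os_months=round(o.os_months, 4), os_event=int(o.os_event),
                best_response=o.best_response.value,
                sd_duration_months="" if o.sd_duration_months is None
                                   else round(o.sd_duration_months, 4),
            ))
            score_rows.append(dict(
                patient_id=p.patient_id,
                score_percent=self.scores[p.patient_id],
                group=self.groups[p.patient_id],
            ))
        return {
            "patients": self.demographics.copy(),
            "alterations": pd.DataFrame(alt_rows),
            "biomarkers": pd.DataFrame(bm_rows),
            "treatments": pd.DataFrame(trt_rows),
            "outcomes": pd.DataFrame(out_rows),
            "scores": pd.DataFrame(score_rows),
        }


def _draw_assay(rng: np.random.Generator, assay_id: str, assay_type: str,
                freqs: dict[str, float], max_count: int) -> AssayResult:
    genes = list(freqs)
    present = rng.random(len(genes)) < np.asarray([freqs[g] for g in genes])
    chosen = [g for g, keep in zip(genes, present) if keep][:max_count]
    alts = [
        Alteration(gene=g, alteration_class=_alteration_class(g),
                   assay_id=assay_id)
        for g in chosen
    ]
    return AssayResult(assay_id=assay_id, assay_type=assay_type, alterations=alts)


def _draw_biomarkers(rng: np.random.Generator, cfg: SimulationConfig) -> ImmuneBiomarkers:
    tmb = None
    if rng.random() < cfg.tmb_tested_prob:
        cat = rng.choice(3, p=np.asarray(cfg.tmb_category_probs))
        if cat == 0:
            tmb = float(rng.uniform(0, 5))
        elif cat == 1:
            tmb = float(rng.uniform(6, 19))
        else:
            tmb = float(rng.uniform(20, 45))
    msi = MSIStatus.UNKNOWN
    if rng.random() < cfg.msi_tested_prob:
        msi = MSIStatus.MSI_HIGH if rng.random() < cfg.msi_high_prob else MSIStatus.STABLE
    pdl1 = None
    if rng.random() < cfg.pdl1_tested_prob:
        if rng.random() < cfg.pdl1_positive_prob:
            if rng.random() < cfg.pdl1_high_given_positive:
                pdl1 = float(rng.uniform(50, 100))
            else:
                pdl1 = float(rng.uniform(1, 50))
        else:
            pdl1 = float(rng.uniform(0, 1))
    er = IHCStatus.POSITIVE if rng.random() < cfg.er_positive_prob else IHCStatus.NEGATIVE
    ar = IHCStatus.POSITIVE if rng.random() < cfg.ar_positive_prob else IHCStatus.NEGATIVE
    return ImmuneBiomarkers(tmb_mut_per_mb=tmb, msi_status=msi, pdl1_percent=pdl1,
                            er_ihc=er, ar_ihc=ar)


def _gene_to_drugs(kb: KnowledgeBase) -> dict[str, list[str]]:
    """Invert effective target sets (synergy pairs offered together)."""
    mapping: dict[str, list[str]] = {}
    for name in sorted(kb.drugs):
        entry = kb.drugs[name]
        if entry.drug_class is DrugClass.CHECKPOINT_INHIBITOR:
            continue
        for gene in sorted(effective_target_genes(entry, kb)):
            mapping.setdefault(gene, []).append(name)
    return mapping


def _draw_regimen(
    rng: np.random.Generator,
    profile: PatientProfile,
    kb: KnowledgeBase,
    policy: str,
) -> list[str]:
    if policy == "unmatched":
        return ["gemcitabine", "paclitaxel"]
    if policy == "random":
        names = sorted(kb.drugs)
        k = int(rng.integers(1, 4))
        return list(rng.choice(names, size=k, replace=False))

    # matched_rich: target as many of the patient's genes as possible
    gene_map = _gene_to_drugs(kb)
    genes = sorted({a.gene for ar in profile.assay_results for a in ar.alterations})
    synergy_partner = {e.name: e.synergy_partner for e in kb.drugs.values()
                      if e.synergy_partner is not None}
    regimen: list[str] = []
    for gene in genes:
        if len(regimen) >= 4:
            break
        options = gene_map.get(gene)
        if not options:
            continue
        drug = str(rng.choice(options))
        if drug in regimen:
            continue
        regimen.append(drug)
        sp = synergy_partner.get(drug)
        if sp is not None and sp.drug not in regimen:
            regimen.append(sp.drug)
    bm = profile.biomarkers
    immune_eligible = (
        bm.msi_status is MSIStatus.MSI_HIGH
        or (bm.tmb_mut_per_mb is not None and bm.tmb_mut_per_mb >= 6)
        or (bm.pdl1_percent is not None and bm.pdl1_percent >= 1)
    )
    if immune_eligible and rng.random() < 0.8:
        regimen.append("pembrolizumab" if rng.random() < 0.5 else "nivolumab")
    if bm.er_ihc is IHCStatus.POSITIVE and rng.random() < 0.5:
        regimen.append("letrozole")
    if not regimen:
        regimen = ["carboplatin", "gemcitabine"]
    return regimen


def simulate_outcomes(
    group_labels: Sequence[str],
    outcome_model: OutcomeModel,
    seed: int | np.random.Generator,
) -> list[OutcomeRecord]:
    """Draw PFS/OS/response outcomes for scored patients.

    PFS is exponential with the group's median; OS adds an independent
    exponential post-progression survival so OS >= PFS always holds.
    Best response is assigned consistently with the drawn benefit
    indicator: responders (PR) confer benefit at any PFS, while stable
    disease only counts with >= 6 months' duration.  Censoring is
    administrative and independent of the event process: each patient
    gets a follow-up time drawn uniformly on (0, b], with b calibrated
    per group so the expected fraction of censored PFS times equals
    ``censoring_fraction``; PFS and OS are both truncated at that same
    follow-up time, so recorded OS never precedes recorded PFS.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = outcome_model

    def uniform_bound(median: float) -> float:
        # b such that P(U(0,b) < Exp(rate)) = censoring_fraction,
        # i.e. (1 - exp(-rate*b)) / (rate*b) = f; solved by bisection.
        f = m.censoring_fraction
        if f <= 0:
            return math.inf
        rate = math.log(2) / median
        lo, hi = 1e-9, 1e6
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if (1 - math.exp(-mid)) / mid > f:
                lo = mid
            else:
                hi = mid
        return lo / rate

    bounds = {"high": uniform_bound(m.pfs_median_high),
              "low": uniform_bound(m.pfs_median_low)}
    records: list[OutcomeRecord] = []
    for g in group_labels:
        high = g == "high"
        pfs_med = m.pfs_median_high if high else m.pfs_median_low
        os_med = m.os_median_high if high else m.os_median_low
        benefit_p = m.benefit_prob_high if high else m.benefit_prob_low
        pfs = rng.exponential(pfs_med / math.log(2))
        post = rng.exponential(max(os_med - pfs_med, 0.1) / math.log(2))
        os_ = pfs + post
        benefit = rng.random() < benefit_p
        if benefit:
            if pfs >= 6 and rng.random() < 0.5:
                response, sd_dur = BestResponse.SD, pfs
            else:
                response, sd_dur = BestResponse.PR, None
        else:
            if pfs < 6 and rng.random() < 0.3:
                response, sd_dur = BestResponse.SD, pfs
            else:
                response, sd_dur = BestResponse.PD, None
        b = bounds["high" if high else "low"]
        follow_up = rng.uniform(0, b) if math.isfinite(b) else math.inf
        if follow_up < pfs:
            fu = max(follow_up, 1e-3)
            records.append(OutcomeRecord(
                pfs_months=fu, pfs_event=False,
                os_months=fu, os_event=False,
                best_response=response, sd_duration_months=(
                    min(sd_dur, fu) if sd_dur is not None else None),
            ))
        elif follow_up < os_:
            records.append(OutcomeRecord(
                pfs_months=max(pfs, 1e-3), pfs_event=True,
                os_months=max(follow_up, 1e-3), os_event=False,
                best_response=response, sd_duration_months=sd_dur,
            ))
        else:
            records.append(OutcomeRecord(
                pfs_months=max(pfs, 1e-3), pfs_event=True,
                os_months=max(os_, 1e-3), os_event=True,
                best_response=response, sd_duration_months=sd_dur,
            ))
    return records


def simulate_cohort(
    config: SimulationConfig, kb: Optional[KnowledgeBase] = None
) -> SimulatedCohort:
    """Generate a full synthetic cohort, scored by the real engine.

    Deterministic given ``config.seed``.
    """
    kb = kb or default_kb()
    rng = np.random.default_rng(config.seed)
    profiles: list[PatientProfile] = []
    demo_rows = []
    histologies = ["adenocarcinoma", "neuroendocrine", "squamous",
                   "poorly_differentiated", "other"]
    histo_p = np.asarray([0.54, 0.19, 0.10, 0.14, 0.03])
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        assays = []
        has_tissue = rng.random() < config.p_tissue_assay
        has_cfdna = rng.random() < config.p_cfdna_assay
        if not (has_tissue or has_cfdna):
            has_tissue = True  # every patient has at least one assay
        if has_tissue:
            assays.append(_draw_assay(rng, f"{pid}-T", "tissue_ngs",
                                      config.tissue_gene_freqs,
                                      config.tissue_max_alterations))
        if has_cfdna:
            assays.append(_draw_assay(rng, f"{pid}-B", "cfdna",
                                      config.cfdna_gene_freqs,
                                      config.cfdna_max_alterations))
        profiles.append(PatientProfile(
            patient_id=pid, assay_results=assays,
            biomarkers=_draw_biomarkers(rng, config),
        ))
        demo_rows.append(dict(
            patient_id=pid,
            age=int(rng.integers(21, 96)),
            sex="female" if rng.random() < 0.61 else "male",
            histology=str(rng.choice(histologies, p=histo_p)),
        ))

    regimens, scores, groups = {}, {}, {}
    for p in profiles:
        regimen = _draw_regimen(rng, p, kb, config.regimen_policy)
        result = compute_matching_score(p, regimen, kb)
        regimens[p.patient_id] = regimen
        scores[p.patient_id] = result.score_percent
        groups[p.patient_id] = dichotomize_score(result.score_percent, config.cutoff)

    labels = [groups[p.patient_id] for p in profiles]
    outcome_list = simulate_outcomes(labels, config.outcome_model, rng)
    outcomes = {p.patient_id: o for p, o in zip(profiles, outcome_list)}
    return SimulatedCohort(
        profiles=profiles, regimens=regimens, scores=scores, groups=groups,
        outcomes=outcomes, demographics=pd.DataFrame(demo_rows),
    )
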