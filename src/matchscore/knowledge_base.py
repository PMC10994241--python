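"""Drug-to-target knowledge base for Matching Score computation.

A :class:`KnowledgeBase` maps drug names (case-insensitively, with
trade-name aliases) to :class:`DrugEntry` records describing which gene
products each drug is considered "matched" to.  Three field conventions
are encoded here rather than at scoring time:

* anti-VEGF/VEGFR agents (antibodies or small molecules) additionally
  match *TP53*-aberrant tumours, reflecting the association between TP53
  loss and VEGFA up-regulation;
* PARP inhibitors and platinum cytotoxics match alterations in
  BRCA-related (homologous-recombination) genes;
* FDA-approved synergistic combinations (dabrafenib+trametinib on BRAF,
  pertuzumab+trastuzumab on ERBB2) are recorded as synergy pairs so the
  scoring engine can double-count their shared target.

Small-molecule target lists are curated offline (low IC50, or a direct
downstream effector of the aberrant gene product, in which case the
upstream gene is listed); no pharmacology is computed at runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

__all__ = [
    "DrugClass",
    "SynergyPartner",
    "DrugEntry",
    "KnowledgeBase",
    "KBError",
    "DrugResolutionError",
    "default_kb",
    "load_kb",
    "write_kb",
    "effective_target_genes",
    "DEFAULT_BRCA_RELATED_GENES",
]


class KBError(ValueError):
    """Raised when a knowledge-base file fails validation."""


class DrugResolutionError(KeyError):
    """Raised when a regimen names drugs absent from the knowledge base."""

    def __init__(self, names: Iterable[str]):
        self.names = sorted(set(names))
        super().__init__(f"unknown drug name(s): {', '.join(self.names)}")


class DrugClass(str, Enum):
    SMALL_MOLECULE = "small_molecule"
    MONOCLONAL_ANTIBODY = "monoclonal_antibody"
    CHECKPOINT_INHIBITOR = "checkpoint_inhibitor"
    PARP_INHIBITOR = "parp_inhibitor"
    PLATINUM = "platinum"
    HORMONE_MODULATOR = "hormone_modulator"
    CYTOTOXIC_OTHER = "cytotoxic_other"


#: Homologous-recombination repair genes treated as PARP/platinum-matched.
DEFAULT_BRCA_RELATED_GENES = frozenset(
    {"BRCA1", "BRCA2", "PALB2", "ATM", "BARD1", "BRIP1", "RAD51C", "RAD51D"}
)


@dataclass(frozen=True)
class SynergyPartner:
    """The other half of an FDA-approved synergistic combination."""

    drug: str
    gene: str


@dataclass(frozen=True)
class DrugEntry:
    name: str
    drug_class: DrugClass
    target_genes: frozenset[str] = frozenset()
    synergy_partner: Optional[SynergyPartner] = None
    anti_vegf: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise KBError("drug name must be non-empty")
        if self.drug_class is DrugClass.CHECKPOINT_INHIBITOR and self.target_genes:
            raise KBError(
                f"checkpoint inhibitor {self.name!r} must have an empty target set"
            )


@dataclass
class KnowledgeBase:
    """Validated collection of drug entries with matching conventions.

    Lookups are case-insensitive and honour the ``aliases`` map
    (trade name -> canonical name).
    """

    drugs: dict[str, DrugEntry] = field(default_factory=dict)
    brca_related_genes: frozenset[str] = DEFAULT_BRCA_RELATED_GENES
    tp53_vegf_rule_enabled: bool = True
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.drugs = {k.lower(): v for k, v in self.drugs.items()}
        self.aliases = {k.lower(): v.lower() for k, v in self.aliases.items()}
        self.validate()

    # -- lookup -----------------------------------------------------------
    def resolve(self, name: str) -> DrugEntry:
        key = name.strip().lower()
        key = self.aliases.get(key, key)
        try:
            return self.drugs[key]
        except KeyError:
            raise DrugResolutionError([name]) from None

    def resolve_regimen(self, regimen: Iterable[str]) -> list[DrugEntry]:
        entries, missing = [], []
        for name in regimen:
            try:
                entries.append(self.resolve(name))
            except DrugResolutionError:
                missing.append(name)
        if missing:
            raise DrugResolutionError(missing)
        return entries

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
            return True
        except DrugResolutionError:
            return False

    @property
    def synergy_pairs(self) -> list[tuple[str, str, str]]:
        """Unique (drugA, drugB, gene) triples, A < B lexicographically."""
        pairs = set()
        for entry in self.drugs.values():
            sp = entry.synergy_partner
            if sp is not None:
                a, b = sorted((entry.name.lower(), sp.drug.lower()))
                pairs.add((a, b, sp.gene))
        return sorted(pairs)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for key, entry in self.drugs.items():
            if entry.name.lower() != key:
                raise KBError(f"entry key {key!r} does not match name {entry.name!r}")
            sp = entry.synergy_partner
            if sp is not None:
                if sp.drug.lower() not in self.drugs:
                    raise KBError(
                        f"synergy partner {sp.drug!r} of {entry.name!r} "
                        "is not in the knowledge base"
                    )
                partner = self.drugs[sp.drug.lower()]
                for e in (entry, partner):
                    if sp.gene not in effective_target_genes(e, self):
                        raise KBError(
                            f"synergy gene {sp.gene!r} is not an effective target "
                            f"of {e.name!r}"
                        )
        for alias, target in self.aliases.items():
            if target not in self.drugs:
                raise KBError(f"alias {alias!r} points to unknown drug {target!r}")


def effective_target_genes(drug: DrugEntry, kb: KnowledgeBase) -> frozenset[str]:
    """Curated targets plus the KB-level matching conventions.

    Adds TP53 for anti-VEGF/VEGFR agents (when the rule is enabled) and
    the BRCA-related gene set for PARP inhibitors and platinums.
    """
    genes = set(drug.target_genes)
    if drug.anti_vegf and kb.tp53_vegf_rule_enabled:
        genes.add("TP53")
    if drug.drug_class in (DrugClass.PARP_INHIBITOR, DrugClass.PLATINUM):
        genes |= kb.brca_related_genes
    return frozenset(genes)


def _entry(name, cls, targets=(), partner=None, anti_vegf=False) -> DrugEntry:
    return DrugEntry(
        name=name,
        drug_class=cls,
        target_genes=frozenset(targets),
        synergy_partner=partner,
        anti_vegf=anti_vegf,
    )


def default_kb() -> KnowledgeBase:
    """Built-in illustrative mini knowledge base.

    Covers each drug class and matching convention; it is not a
    reconstruction of any particular study's curation.
    """
    C = DrugClass
    entries = [
        _entry("dabrafenib", C.SMALL_MOLECULE, {"BRAF"},
               partner=SynergyPartner("trametinib", "BRAF")),
        _entry("trametinib", C.SMALL_MOLECULE, {"BRAF", "KRAS", "NRAS"},
               partner=SynergyPartner("dabrafenib", "BRAF")),
        _entry("pertuzumab", C.MONOCLONAL_ANTIBODY, {"ERBB2"},
               partner=SynergyPartner("trastuzumab", "ERBB2")),
        _entry("trastuzumab", C.MONOCLONAL_ANTIBODY, {"ERBB2"},
               partner=SynergyPartner("pertuzumab", "ERBB2")),
        _entry("letrozole", C.HORMONE_MODULATOR, {"ER", "ESR1"}),
        _entry("enzalutamide", C.HORMONE_MODULATOR, {"AR"}),
        _entry("bevacizumab", C.MONOCLONAL_ANTIBODY, {"VEGFA"}, anti_vegf=True),
        _entry("pazopanib", C.SMALL_MOLECULE,
               {"KDR", "FLT1", "FLT4", "KIT", "PDGFRA", "PDGFRB"}, anti_vegf=True),
        _entry("olaparib", C.PARP_INHIBITOR),
        _entry("carboplatin", C.PLATINUM),
        _entry("cisplatin", C.PLATINUM),
        _entry("pembrolizumab", C.CHECKPOINT_INHIBITOR),
        _entry("nivolumab", C.CHECKPOINT_INHIBITOR),
        _entry("imatinib", C.SMALL_MOLECULE, {"KIT", "PDGFRA", "PDGFRB", "ABL1"}),
        _entry("erlotinib", C.SMALL_MOLECULE, {"EGFR"}),
        _entry("alpelisib", C.SMALL_MOLECULE, {"PIK3CA"}),
        _entry("palbociclib", C.SMALL_MOLECULE, {"CDK4", "CDK6", "CDKN2A"}),
        _entry("everolimus", C.SMALL_MOLECULE, {"MTOR", "PTEN", "TSC1", "TSC2"}),
        _entry("crizotinib", C.SMALL_MOLECULE, {"ALK", "MET", "ROS1"}),
        _entry("gemcitabine", C.CYTOTOXIC_OTHER),
        _entry("paclitaxel", C.CYTOTOXIC_OTHER),
    ]
    aliases = {
        "avastin": "bevacizumab",
        "keytruda": "pembrolizumab",
        "opdivo": "nivolumab",
        "herceptin": "trastuzumab",
        "gleevec": "imatinib",
    }
    return KnowledgeBase(drugs={e.name: e for e in entries}, aliases=aliases)


# -- serialisation --------------------------------------------------------

def _kb_to_dict(kb: KnowledgeBase) -> dict:
    drugs = []
    for name in sorted(kb.drugs):
        e = kb.drugs[name]
        d: dict = {
            "name": e.name,
            "class": e.drug_class.value,
            "targets": sorted(e.target_genes),
        }
        if e.synergy_partner is not None:
            d["synergy_partner"] = {
                "drug": e.synergy_partner.drug,
                "gene": e.synergy_partner.gene,
            }
        if e.anti_vegf:
            d["anti_vegf"] = True
        drugs.append(d)
    return {
        "drugs": drugs,
        "brca_related_genes": sorted(kb.brca_related_genes),
        "tp53_vegf_rule_enabled": kb.tp53_vegf_rule_enabled,
        "aliases": dict(sorted(kb.aliases.items())),
    }


def _kb_from_dict(data: Mapping) -> KnowledgeBase:
    if not isinstance(data, Mapping) or "drugs" not in data:
        raise KBError("knowledge base file must contain a 'drugs' list")
    drugs: dict[str, DrugEntry] = {}
    for raw in data["drugs"]:
        name = raw.get("name", "")
        if name.lower() in drugs:
            raise KBError(f"duplicate drug name {name!r}")
        try:
            cls = DrugClass(raw.get("class"))
        except ValueError:
            raise KBError(
                f"unknown drug class {raw.get('class')!r} for {name!r}"
            ) from None
        sp_raw = raw.get("synergy_partner")
        partner = None
        if sp_raw is not None:
            partner = SynergyPartner(drug=sp_raw["drug"], gene=sp_raw["gene"])
        drugs[name.lower()] = _entry(
            name,
            cls,
            raw.get("targets", ()),
            partner=partner,
            anti_vegf=bool(raw.get("anti_vegf", False)),
        )
    return KnowledgeBase(
        drugs=drugs,
        brca_related_genes=frozenset(
            data.get("brca_related_genes", DEFAULT_BRCA_RELATED_GENES)
        ),
        tp53_vegf_rule_enabled=bool(data.get("tp53_vegf_rule_enabled", True)),
        aliases=dict(data.get("aliases", {})),
    )


def load_kb(path: str | Path, format: Optional[str] = None) -> KnowledgeBase:
    """Load and validate a knowledge base from a JSON or YAML file.

    ``format`` defaults to the file extension (.json / .yaml / .yml).
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "yaml")
    text = path.read_text(encoding="utf-8")
    try:
        data = json.loads(text) if fmt == "json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise KBError(f"cannot parse {path}: {exc}") from exc
    return _kb_from_dict(data)


def write_kb(kb: KnowledgeBase, path: str | Path, format: Optional[str] = None) -> None:
    """Serialise a knowledge base to JSON or YAML (round-trips with load_kb)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "yaml")
    data = _kb_to_dict(kb)
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
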