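from __future__ import annotations

import numpy as np
import pytest

from matchscore.knowledge_base import default_kb
from matchscore.patient_model import (
    Alteration,
    AlterationClass,
    AssayResult,
    ImmuneBiomarkers,
    PatientProfile,
)


@pytest.fixture(scope="session")
def kb():
    return default_kb()


def make_profile(genes, patient_id="p1", assay_id="A1", assay_type="tissue_ngs",
                 biomarkers=None, alteration_class=AlterationClass.MUTATION):
    """Single-assay profile with one mutation per gene."""
    alts = [Alteration(g, alteration_class, assay_id) for g in genes]
    return PatientProfile(
        patient_id=patient_id,
        assay_results=[AssayResult(assay_id, assay_type, alts)],
        biomarkers=biomarkers or ImmuneBiomarkers(),
    )


def random_profile(rng: np.random.Generator, gene_pool, max_units=6):
    """Random small profile spread over one or two assays."""
    n = int(rng.integers(0, max_units + 1))
    genes = list(rng.choice(gene_pool, size=n, replace=True))
    classes = list(AlterationClass)
    n_assays = int(rng.integers(1, 3))
    assays = {
        f"A{k}": AssayResult(f"A{k}", "tissue_ngs" if k == 0 else "cfdna", [])
        for k in range(n_assays)
    }
    for g in genes:
        aid = f"A{int(rng.integers(0, n_assays))}"
        cls = classes[int(rng.integers(0, len(classes)))]
        assays[aid].alterations.append(Alteration(g, cls, aid))
    from matchscore.patient_model import IHCStatus, MSIStatus

    msi = [MSIStatus.MSI_HIGH, MSIStatus.STABLE, MSIStatus.UNKNOWN]
    ihc = [IHCStatus.POSITIVE, IHCStatus.NEGATIVE, IHCStatus.UNKNOWN]
    bm = ImmuneBiomarkers(
        tmb_mut_per_mb=float(rng.uniform(0, 30)) if rng.random() < 0.5 else None,
        pdl1_percent=float(rng.uniform(0, 100)) if rng.random() < 0.5 else None,
        msi_status=msi[int(rng.integers(0, 3))],
        er_ihc=ihc[int(rng.integers(0, 3))],
        ar_ihc=ihc[int(rng.integers(0, 3))],
    )
    return PatientProfile("px", list(assays.values()), bm)
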