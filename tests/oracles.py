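"""Independent oracles used only by the test suite.

Each function re-derives its quantity from first principles (literal
rule enumeration, dense grid search, exact combinatorics) without going
through the package's implementation paths.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_score(profile, regimen, kb) -> Fraction:
    """Literal re-application of the Matching Score rules.

    Enumerates every (unit, drug) pair directly from the raw assay
    results and knowledge-base fields; returns the exact percent score.
    """
    entries = [kb.resolve(d) for d in regimen]
    checkpoint = [e for e in entries if e.drug_class.value == "checkpoint_inhibitor"]
    others = [e for e in entries if e.drug_class.value != "checkpoint_inhibitor"]

    def targets(e):
        g = set(e.target_genes)
        if e.anti_vegf and kb.tp53_vegf_rule_enabled:
            g.add("TP53")
        if e.drug_class.value in ("parp_inhibitor", "platinum"):
            g |= set(kb.brca_related_genes)
        return g

    # rule (a)/(c): per assay, one unit per distinct (gene, class)
    units = []
    seen = set()
    for ar in profile.assay_results:
        for alt in ar.alterations:
            key = (ar.assay_id, alt.gene, alt.alteration_class.value)
            if key not in seen:
                seen.add(key)
                units.append(alt.gene)

    # rule (b): genes whose synergy pair is fully present in the regimen
    names = {e.name.lower() for e in others}
    syn_genes = set()
    for e in kb.drugs.values():
        sp = e.synergy_partner
        if sp and e.name.lower() in names and sp.drug.lower() in names:
            syn_genes.add(sp.gene)

    num = den = 0
    for g in units:
        matched = any(g in targets(e) for e in others)
        w = 2 if (matched and g in syn_genes) else 1
        den += w
        if matched:
            num += w

    # rule (d): hormone receptor positivity + hormone modulator
    bm = profile.biomarkers
    for marker, status in (("ER", bm.er_ihc), ("AR", bm.ar_ihc)):
        if status.value == "positive" and any(
            e.drug_class.value == "hormone_modulator" and marker in targets(e)
            for e in others
        ):
            num += 1
            den += 1

    # checkpoint tiers
    tier = "absent"
    if checkpoint:
        tmb = bm.tmb_mut_per_mb
        pdl1 = bm.pdl1_percent
        if (
            bm.msi_status.value == "msi_high"
            or (tmb is not None and tmb >= 20)
            or (pdl1 is not None and pdl1 >= 50)
        ):
            tier = "full"
        elif (tmb is not None and 6 <= tmb < 20) or (
            pdl1 is not None and 1 <= pdl1 < 50
        ):
            tier = "half"
        else:
            tier = "zero"

    if tier == "full":
        return Fraction(100)
    if tier == "half":
        score = Fraction(50) + (Fraction(100 * num, 2 * den) if den else Fraction(0))
    else:
        score = Fraction(100 * num, den) if den else Fraction(0)
    return min(score, Fraction(100))


def grid_cox_loghr(times, events, x, lo=-5.0, hi=5.0, n_coarse=20001):
    """Dense grid-search maximiser of the Cox partial likelihood.

    Single covariate, Breslow/Efron-free (assumes no tied event times).
    Two-stage grid gives ~1e-6 resolution on the log hazard ratio.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)

    def loglik(betas):
        ll = np.zeros_like(betas)
        for i in np.where(events)[0]:
            risk = x[times >= times[i]]
            ll += betas * x[i] - np.log(
                np.exp(np.outer(betas, risk)).sum(axis=1)
            )
        return ll

    grid = np.linspace(lo, hi, n_coarse)
    b0 = grid[np.argmax(loglik(grid))]
    step = (hi - lo) / (n_coarse - 1)
    fine = np.linspace(b0 - step, b0 + step, 4001)
    return float(fine[np.argmax(loglik(fine))])


def fisher_exact_enum(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(k):
        return comb(r1, k) * comb(n - r1, c1 - k) / comb(n, c1)

    p_obs = pmf(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))
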