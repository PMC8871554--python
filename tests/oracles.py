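"""Independent reference implementations used as test oracles.

Deliberately written as plain exhaustive loops over the raw data structures,
sharing no code path with the package's scorer or rank test.
"""

from itertools import combinations

import numpy as np

from tripod_adherence import ChecklistDefinition, RatingSet, Response, StudyType


def oracle_study_score(
    consensus: RatingSet, study_type: StudyType, defn: ChecklistDefinition
) -> tuple[int, int]:
    """(numerator, denominator) by brute-force looping over every component."""
    num = 0
    den = 0
    for comp in defn.components:
        if comp.component_id == "21" or comp.excluded_from_score:
            continue
        applies = (
            comp.applicability.value == "both"
            or study_type == StudyType.DEVELOPMENT_AND_VALIDATION
            or (
                study_type == StudyType.DEVELOPMENT
                and comp.applicability.value == "development_only"
            )
            or (
                study_type == StudyType.VALIDATION
                and comp.applicability.value == "validation_only"
            )
        )
        if not applies:
            continue
        responses = [
            consensus.responses[(comp.component_id, e.element_id)]
            for e in comp.elements
        ]
        non_na = [r for r in responses if r != Response.NOT_APPLICABLE]
        if comp.na_eligible and len(non_na) == 0:
            continue  # rated not applicable: out of the denominator
        den += 1
        if all(r in (Response.YES, Response.REFERENCED) for r in non_na):
            num += 1
    return num, den


def oracle_disagreement_count(rating_sets) -> int:
    """Brute-force scan over all (study, component, element) triples."""
    studies = sorted({rs.study_id for rs in rating_sets})
    count = 0
    for sid in studies:
        sets = [rs for rs in rating_sets if rs.study_id == sid]
        keys = set()
        for rs in sets:
            keys |= set(rs.responses)
        for key in keys:
            responses = {rs.responses[key] for rs in sets if key in rs.responses}
            if len(responses) >= 2:
                count += 1
    return count


def oracle_mann_whitney(x, y) -> tuple[float, float]:
    """(U, two-sided p) by enumerating every label assignment.

    Midranks computed by hand; the p-value sums the probabilities of
    assignments at least as extreme as observed in |U - n1*n2/2|.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    pooled = x + y

    def midranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    ranks = midranks(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    expected = n1 * n2 / 2
    us = []
    for idx in combinations(range(n1 + n2), n1):
        us.append(sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2)
    d = abs(u_obs - expected)
    p = sum(1 for u in us if abs(u - expected) >= d - 1e-9) / len(us)
    return u_obs, p


def oracle_beta_loglik(y, mu, phi) -> float:
    """Beta log-likelihood at constant mean/precision, via scipy's pdf."""
    from scipy.stats import beta as beta_dist

    a, b = mu * phi, (1 - mu) * phi
    return float(np.sum(beta_dist.logpdf(np.asarray(y, dtype=float), a, b)))


def grid_search_beta_ml(y, n_refine: int = 6) -> tuple[float, float, float]:
    """Intercept-only ML by successive 2-d grid refinement over (mu, phi).

    Returns (mu_hat, phi_hat, loglik). Independent of any gradient-based
    fitting; accuracy of the maximised log-likelihood is driven well below
    1e-4 by the refinement depth.
    """
    lo_mu, hi_mu = 0.01, 0.99
    lo_lp, hi_lp = np.log(0.1), np.log(5000.0)
    best = (0.5, 1.0, -np.inf)
    for _ in range(n_refine):
        mus = np.linspace(lo_mu, hi_mu, 61)
        lps = np.linspace(lo_lp, hi_lp, 61)
        for mu in mus:
            for lp in lps:
                ll = oracle_beta_loglik(y, mu, np.exp(lp))
                if ll > best[2]:
                    best = (float(mu), float(np.exp(lp)), ll)
        dmu = (hi_mu - lo_mu) / 60
        dlp = (hi_lp - lo_lp) / 60
        lo_mu = max(1e-6, best[0] - 2 * dmu)
        hi_mu = min(1 - 1e-6, best[0] + 2 * dmu)
        lo_lp = np.log(best[1]) - 2 * dlp
        hi_lp = np.log(best[1]) + 2 * dlp
    return best


def random_consensus(rng, defn: ChecklistDefinition, study_type: StudyType, study_id="S"):
    """A random but schema-valid complete consensus rating set."""
    responses = {}
    for comp in defn.components:
        applies = (
            comp.applicability.value == "both"
            or study_type == StudyType.DEVELOPMENT_AND_VALIDATION
            or (
                study_type == StudyType.DEVELOPMENT
                and comp.applicability.value == "development_only"
            )
            or (
                study_type == StudyType.VALIDATION
                and comp.applicability.value == "validation_only"
            )
        )
        if not applies:
            continue
        if comp.na_eligible and rng.random() < 0.2:
            for e in comp.elements:
                responses[(comp.component_id, e.element_id)] = Response.NOT_APPLICABLE
            continue
        for e in comp.elements:
            opts = [Response.YES, Response.NO]
            if e.referenced_allowed:
                opts.append(Response.REFERENCED)
            if e.na_allowed:
                opts.append(Response.NOT_APPLICABLE)
            responses[(comp.component_id, e.element_id)] = opts[
                int(rng.integers(len(opts)))
            ]
        # avoid the invalid all-NA state for non-eligible components
        if not comp.na_eligible and all(
            responses[(comp.component_id, e.element_id)] == Response.NOT_APPLICABLE
            for e in comp.elements
        ):
            e0 = comp.elements[0]
            responses[(comp.component_id, e0.element_id)] = Response.NO
    return RatingSet(study_id=study_id, reviewer_id="consensus", responses=responses)
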