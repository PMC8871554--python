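"""Synthetic rating corpora with the statistical structure the analysis assumes.

Each study draws covariates (type, year, journal category, impact factor),
gets a latent adherence probability theta from a beta distribution whose
mean and precision depend on those covariates through the same logit / log
links the trend model fits, and then adheres to each applicable checklist
component independently with probability theta.  Adhered components are
rendered as all-positive element responses; a non-adhered component carries
exactly one "no".  NA-eligible components are rated not-applicable at a
configurable rate, and per-reviewer copies are perturbed element-wise to
create realistic disagreements.  Everything is reproducible from the seed.

The default configuration mirrors a corpus of 42 melanoma risk-prediction
studies: 35 development-only and 7 development-plus-validation, published
1988-2021 with publication activity concentrated in recent years, six
journal subject categories with fixed counts (15 Oncology, 12 Dermatology,
4 + 4 + 2 + 3 across the rest), two non-original publications and three
studies citing the reporting guideline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .checklist import ChecklistDefinition, StudyType, load_tripod
from .ratings import (
    CONSENSUS_REVIEWER,
    RatingSet,
    Response,
    StudyRecord,
    apply_consensus,
    find_disagreements,
    write_ratings,
    write_studies,
)
from .scoring import score_corpus
from .betareg import ModelSpec, fit_trend, coefficient_tests

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_corpus",
    "recovery_benchmark_config",
    "truth_adjudications",
    "write_corpus",
    "recovery_harness",
    "RecoveryReport",
]

_DEFAULT_TYPE_MIX = {
    StudyType.DEVELOPMENT: Fraction(35, 42),
    StudyType.DEVELOPMENT_AND_VALIDATION: Fraction(7, 42),
    StudyType.VALIDATION: Fraction(0),
}

# Relative category frequencies of the reference corpus (counts 15, 12, 4,
# 4, 2 and 3; normalised to sum to one).
_DEFAULT_CATEGORY_PROBS = {
    "Oncology": Fraction(15, 40),
    "Dermatology": Fraction(12, 40),
    "Medicine General & Internal": Fraction(4, 40),
    "Multidisciplinary Sciences": Fraction(4, 40),
    "Public Environmental & Occupational Health": Fraction(2, 40),
    "Other": Fraction(3, 40),
}

# Logit-scale category offsets against the Dermatology reference, ordered so
# dermatology journals have the highest adjusted mean and "Other" the lowest.
_DEFAULT_CATEGORY_EFFECTS = {
    "Oncology": -0.184,
    "Medicine General & Internal": -0.080,
    "Multidisciplinary Sciences": -0.459,
    "Public Environmental & Occupational Health": -0.411,
    "Other": -0.570,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the corpus generator; defaults are the reference corpus.

    ``true_beta`` holds the mean-submodel coefficients on the logit scale
    (keys: ``intercept``, ``year`` per year after centering,
    ``impact_factor`` per impact-factor point, ``non_original`` — the offset
    for publications without the regular article structure, which score
    systematically lower); ``category_effects`` are logit offsets against
    the reference category; ``true_gamma`` holds the precision-submodel
    coefficients on the log scale.  The default mean intercept puts a
    reference-category study of the centering year at a mean score of 0.62,
    which with the category mix gives a corpus-wide mean near 0.57.
    """

    n_studies: int = 42
    study_type_mix: Mapping[StudyType, Fraction] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_MIX)
    )
    year_range: tuple[int, int] = (1988, 2021)
    category_probabilities: Mapping[str, Fraction] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_PROBS)
    )
    impact_factor_range: tuple[float, float] = (0.0, 26.0)
    n_non_original: int = 2
    n_cites_tripod: int = 3
    true_beta: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 0.506,
            "year": 0.02,
            "impact_factor": 0.0,
            "non_original": -1.0,
        }
    )
    category_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_EFFECTS)
    )
    true_gamma: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": 3.0, "year": -0.03}
    )
    year_centering: float = 2005.0
    n_reviewers: int = 6
    disagreement_rate: float = 0.02
    na_rate: float = 0.25
    referenced_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if abs(float(sum(self.study_type_mix.values())) - 1.0) > 1e-9:
            raise ValueError("study_type_mix probabilities must sum to 1")
        if abs(float(sum(self.category_probabilities.values())) - 1.0) > 1e-9:
            raise ValueError("category_probabilities must sum to 1")
        for name in ("disagreement_rate", "na_rate", "referenced_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (min, max)")
        if self.n_reviewers < 1:
            raise ValueError("need at least one reviewer")


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent quantities behind a generated corpus.

    ``component_adhered`` maps study -> component -> intended adherence for
    every component that received a substantive rating; ``na_components``
    lists the components rated not-applicable.  ``true_ratings`` are the
    unperturbed consensus-grade rating sets the reviewer copies were derived
    from.  ``intended_numerator / intended_denominator`` already exclude the
    score-excluded item, so intended score = numerator / denominator.
    """

    theta: dict[str, float]
    mu: dict[str, float]
    phi: dict[str, float]
    component_adhered: dict[str, dict[str, bool]]
    na_components: dict[str, frozenset[str]]
    intended_numerator: dict[str, int]
    intended_denominator: dict[str, int]
    true_ratings: list[RatingSet]

    def intended_score(self, study_id: str) -> Fraction:
        return Fraction(
            self.intended_numerator[study_id], self.intended_denominator[study_id]
        )


def _largest_remainder_counts(
    probs: Mapping, n: int
) -> dict:
    """Deterministic integer allocation of n across categories."""
    raw = {k: float(p) * n for k, p in probs.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_rem = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), str(k)))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def _allowed_alternatives(elem, current: Response) -> list[Response]:
    opts = [Response.YES, Response.NO]
    if elem.referenced_allowed:
        opts.append(Response.REFERENCED)
    if elem.na_allowed:
        opts.append(Response.NOT_APPLICABLE)
    return [o for o in opts if o is not current]


def generate_corpus(
    config: GeneratorConfig,
    defn: ChecklistDefinition | None = None,
    seed: int | None = None,
) -> tuple[list[StudyRecord], list[RatingSet], SyntheticTruth]:
    """Draw one full corpus: metadata, per-reviewer ratings and latent truth."""
    config.validate()
    defn = defn or load_tripod()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n = config.n_studies
    type_counts = _largest_remainder_counts(config.study_type_mix, n)
    types = [t for t, c in type_counts.items() for _ in range(c)]
    types = [types[i] for i in rng.permutation(n)]

    cat_counts = _largest_remainder_counts(config.category_probabilities, n)
    cats = [c for c, k in cat_counts.items() for _ in range(k)]
    cats = [cats[i] for i in rng.permutation(n)]

    y0, y1 = config.year_range
    year_values = np.arange(y0, y1 + 1)
    weights = year_values - y0 + 1.0  # publication activity rises over time
    years = rng.choice(year_values, size=n, p=weights / weights.sum())

    if_lo, if_hi = config.impact_factor_range
    impact = rng.uniform(if_lo, if_hi, size=n)

    non_orig = set(
        rng.choice(n, size=min(config.n_non_original, n), replace=False)
    )
    # guideline-citing studies can only postdate the guideline (2015)
    eligible = [i for i in range(n) if years[i] >= 2015]
    if len(eligible) < config.n_cites_tripod:
        eligible = list(np.argsort(years)[-config.n_cites_tripod:])
    cites = set(
        rng.choice(eligible, size=min(config.n_cites_tripod, len(eligible)),
                   replace=False)
    )

    width = len(str(n))
    studies: list[StudyRecord] = []
    for i in range(n):
        cat = cats[i]
        studies.append(
            StudyRecord(
                study_id=f"S{i + 1:0{width}d}",
                study_type=types[i],
                publication_year=int(years[i]),
                journal_category=cat,
                # non-JCR journals have no impact factor; recorded as 0
                impact_factor=0.0 if cat == "Other" else round(float(impact[i]), 1),
                is_original_article=i not in non_orig,
                cites_tripod=i in cites,
            )
        )

    b = config.true_beta
    g = config.true_gamma
    theta_d: dict[str, float] = {}
    mu_d: dict[str, float] = {}
    phi_d: dict[str, float] = {}
    comp_adhered: dict[str, dict[str, bool]] = {}
    na_comps: dict[str, frozenset[str]] = {}
    intended_num: dict[str, int] = {}
    intended_den: dict[str, int] = {}
    true_ratings: list[RatingSet] = []
    reviewer_ratings: list[RatingSet] = []
    reviewer_ids = [f"rev{j + 1}" for j in range(config.n_reviewers)]

    for study in studies:
        yc = study.publication_year - config.year_centering
        eta = (
            b.get("intercept", 0.0)
            + b.get("year", 0.0) * yc
            + config.category_effects.get(study.journal_category, 0.0)
            + b.get("impact_factor", 0.0) * study.impact_factor
            + (0.0 if study.is_original_article else b.get("non_original", 0.0))
        )
        mu = 1.0 / (1.0 + np.exp(-eta))
        phi = np.exp(g.get("intercept", 0.0) + g.get("year", 0.0) * yc)
        theta = float(rng.beta(mu * phi, (1.0 - mu) * phi))
        theta_d[study.study_id] = theta
        mu_d[study.study_id] = float(mu)
        phi_d[study.study_id] = float(phi)

        responses: dict[tuple[str, str], Response] = {}
        adhered_map: dict[str, bool] = {}
        na_set: set[str] = set()
        num = den = 0
        for comp in defn.components:
            if not comp.applicability.applies_to(study.study_type):
                continue
            if comp.na_eligible and rng.random() < config.na_rate:
                na_set.add(comp.component_id)
                for elem in comp.elements:
                    responses[(comp.component_id, elem.element_id)] = (
                        Response.NOT_APPLICABLE
                    )
                continue
            adhered = bool(rng.random() < theta)
            adhered_map[comp.component_id] = adhered
            if not comp.excluded_from_score:
                den += 1
                num += adhered
            miss = -1 if adhered else int(rng.integers(len(comp.elements)))
            for k, elem in enumerate(comp.elements):
                if k == miss:
                    r = Response.NO
                elif elem.referenced_allowed and rng.random() < config.referenced_rate:
                    r = Response.REFERENCED
                else:
                    r = Response.YES
                responses[(comp.component_id, elem.element_id)] = r

        comp_adhered[study.study_id] = adhered_map
        na_comps[study.study_id] = frozenset(na_set)
        intended_num[study.study_id] = num
        intended_den[study.study_id] = den
        true_ratings.append(
            RatingSet(
                study_id=study.study_id,
                reviewer_id=CONSENSUS_REVIEWER,
                responses=responses,
            )
        )

        for rid in reviewer_ids:
            copy = dict(responses)
            for (cid, eid), current in responses.items():
                if rng.random() < config.disagreement_rate:
                    elem = defn.component(cid).element(eid)
                    alts = _allowed_alternatives(elem, current)
                    copy[(cid, eid)] = alts[int(rng.integers(len(alts)))]
            reviewer_ratings.append(
                RatingSet(study_id=study.study_id, reviewer_id=rid, responses=copy)
            )

    truth = SyntheticTruth(
        theta=theta_d,
        mu=mu_d,
        phi=phi_d,
        component_adhered=comp_adhered,
        na_components=na_comps,
        intended_numerator=intended_num,
        intended_denominator=intended_den,
        true_ratings=true_ratings,
    )
    return studies, reviewer_ratings, truth


def truth_adjudications(
    truth: SyntheticTruth,
    reviewer_ratings: Sequence[RatingSet],
    defn: ChecklistDefinition | None = None,
) -> dict[tuple[str, str, str], Response]:
    """Adjudication table resolving every reviewer disagreement to the latent
    truth — the synthetic stand-in for consensus meetings plus referees."""
    by_study = {rs.study_id: rs for rs in truth.true_ratings}
    return {
        d.key: by_study[d.study_id].responses[(d.component_id, d.element_id)]
        for d in find_disagreements(reviewer_ratings, defn)
    }


def write_corpus(
    studies: Sequence[StudyRecord],
    reviewer_ratings: Sequence[RatingSet],
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write studies.csv, ratings.csv and truth_ratings.csv into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "studies": out / "studies.csv",
        "ratings": out / "ratings.csv",
        "truth_ratings": out / "truth_ratings.csv",
    }
    write_studies(studies, paths["studies"])
    write_ratings(reviewer_ratings, paths["ratings"])
    write_ratings(truth.true_ratings, paths["truth_ratings"])
    return paths


def recovery_benchmark_config(n_studies: int = 200, seed: int = 0) -> GeneratorConfig:
    """Reference configuration for parameter-recovery experiments.

    A correctly specified year-only model: constant category / impact-factor
    / publication-form effects, mean score 0.57 at the centering year, a
    mean-submodel year slope of 0.03 on the logit scale and constant
    precision exp(3).  A single unperturbed reviewer keeps the rating layer
    deterministic so replicates isolate the sampling noise of the scores.
    """
    return GeneratorConfig(
        n_studies=n_studies,
        true_beta={
            "intercept": 0.282,
            "year": 0.03,
            "impact_factor": 0.0,
            "non_original": 0.0,
        },
        category_effects={},
        true_gamma={"intercept": 3.0, "year": 0.0},
        n_reviewers=1,
        disagreement_rate=0.0,
        n_non_original=0,
        n_cites_tripod=0,
        seed=seed,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Bias and Wald-interval coverage of the trend fit across replicates."""

    parameter_names: tuple[str, ...]
    true_values: dict[str, float]
    estimates: pd.DataFrame  # one row per replicate, one column per parameter
    std_errors: pd.DataFrame
    n_replicates: int

    def bias(self) -> dict[str, float]:
        return {
            p: float(self.estimates[p].mean() - self.true_values[p])
            for p in self.parameter_names
            if p in self.true_values
        }

    def coverage(self, level: float = 0.95) -> dict[str, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        out = {}
        for p in self.parameter_names:
            if p not in self.true_values:
                continue
            lo = self.estimates[p] - z * self.std_errors[p]
            hi = self.estimates[p] + z * self.std_errors[p]
            tv = self.true_values[p]
            out[p] = float(((lo <= tv) & (tv <= hi)).mean())
        return out


def recovery_harness(
    config: GeneratorConfig,
    model_spec: ModelSpec | None = None,
    *,
    n_replicates: int = 100,
    seed: int = 0,
    original_articles_only: bool = True,
) -> RecoveryReport:
    """Run generate -> consensus -> score -> trend repeatedly and collect the
    sampling distribution of the fitted coefficients.

    The trend model defaults to year in both submodels with the generator's
    own centering, so the mean-submodel year coefficient estimates the
    configured ``true_beta['year']`` and the precision-submodel one
    ``true_gamma['year']``.
    """
    defn = load_tripod()
    spec = model_spec or ModelSpec(
        mean_covariates=("year",),
        precision_covariates=("year",),
        year_centering=config.year_centering,
    )
    master = np.random.default_rng(seed)
    rows_est: list[dict[str, float]] = []
    rows_se: list[dict[str, float]] = []
    names: tuple[str, ...] = ()
    for _ in range(n_replicates):
        rep_seed = int(master.integers(2**31 - 1))
        studies, ratings, truth = generate_corpus(config, defn, seed=rep_seed)
        if config.disagreement_rate > 0:
            consensus = apply_consensus(
                ratings, truth_adjudications(truth, ratings, defn)
            )
        else:
            consensus = truth.true_ratings
        corpus = score_corpus(consensus, studies, defn)
        if original_articles_only:
            corpus = [(r, s) for r, s in corpus if s.is_original_article]
        from .scoring import corpus_scores_frame

        fit = fit_trend(corpus_scores_frame(corpus), spec,
                        boundary_compression=True)
        tests = coefficient_tests(fit)
        rows_est.append({t.name: t.estimate for t in tests})
        rows_se.append({t.name: t.std_error for t in tests})
        names = tuple(t.name for t in tests)

    true_values = {
        "mean:const": config.true_beta.get("intercept", 0.0),
        "mean:year": config.true_beta.get("year", 0.0),
        "mean:impact_factor": config.true_beta.get("impact_factor", 0.0),
        "precision:const": config.true_gamma.get("intercept", 0.0),
        "precision:year": config.true_gamma.get("year", 0.0),
    }
    for lvl, eff in config.category_effects.items():
        true_values[f"mean:journal_category[{lvl}]"] = eff
    return RecoveryReport(
        parameter_names=names,
        true_values=true_values,
        estimates=pd.DataFrame(rows_est),
        std_errors=pd.DataFrame(rows_se),
        n_replicates=n_replicates,
    )
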