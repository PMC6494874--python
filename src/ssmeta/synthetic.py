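"""Synthetic effect-size datasets with known ground truth.

The generator emulates the meta-dataset layer of a sexual-selection
experimental-evolution synthesis: ~65 studies each contributing a
handful of treatment comparisons, a skewed distribution of fitness
components, a few taxa, heteroscedastic sampling variances driven by
group sizes and within-group coefficients of variation, and a positive
mean-variance relationship (SD proportional to the mean).

Each record's true standardized effect is

    theta_i = x_i' beta + u_study + u_trait + u_taxon (+ u_effect)

with independent normal level deviations.  Group summaries are then
drawn as normal-sample means (mean ~ N(mu_g, s_g^2/n)) and SDs via
scaled chi-square draws, so the computed Hedges' g has expectation
theta_i to first order and the analytic sampling-variance formulas
used downstream are correct by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .records import EffectRecord, GroupSummary

SEXES_ORDER = ("male", "female", "both")
ENVS_ORDER = ("stressful", "benign")

#: Column order of the sex-by-environment treatment-coded design that a
#: length-6 beta refers to (reference cell: male x benign).
SEX_ENV_COLUMNS = (
    "intercept",
    "sex[both]",
    "sex[female]",
    "environment[stressful]",
    "sex[both]:environment[stressful]",
    "sex[female]:environment[stressful]",
)

DEFAULT_TRAITS = ("fecundity", "lifespan", "offspring viability", "body size")
DEFAULT_TAXA = ("flies", "beetles", "nematodes")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration of a simulated meta-dataset.

    ``beta`` is either length 1 (intercept-only true model) or length 6
    (the sex-by-environment design in :data:`SEX_ENV_COLUMNS` order),
    on the standardized-mean-difference scale.
    """

    n_studies: int = 30
    effects_per_study: tuple[int, int] = (1, 8)
    trait_labels: tuple[str, ...] = DEFAULT_TRAITS
    taxon_labels: tuple[str, ...] = DEFAULT_TAXA
    beta: tuple[float, ...] = (0.2,)
    sigma2_study: float = 0.05
    sigma2_trait: float = 0.01
    sigma2_taxon: float = 0.01
    sigma2_effect: float = 0.0
    group_n_range: tuple[int, int] = (10, 60)
    cv_range: tuple[float, float] = (0.1, 0.4)
    moderator_probs: Optional[dict[tuple[str, str], float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be >= 1")
        lo, hi = self.effects_per_study
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid effects_per_study range")
        for name in ("sigma2_study", "sigma2_trait", "sigma2_taxon", "sigma2_effect"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        nlo, nhi = self.group_n_range
        if not (2 <= nlo <= nhi):
            raise ConfigurationError("group_n_range minimum must be >= 2")
        clo, chi = self.cv_range
        if not (0 < clo <= chi):
            raise ConfigurationError("cv_range must be positive")
        if len(self.beta) not in (1, 6):
            raise ConfigurationError("beta must have length 1 or 6")
        if self.moderator_probs is not None:
            total = sum(self.moderator_probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigurationError(
                    f"moderator cell probabilities must sum to 1, got {total}"
                )


@dataclass
class SimDataset:
    """Generated records plus the ground truth that produced them."""

    records: list[EffectRecord]
    truth: pd.DataFrame  # per-record theta and level deviations
    config: SimConfig


def _default_cell_probs() -> dict[tuple[str, str], float]:
    # Roughly the sex-by-environment mix seen in experimental-evolution
    # syntheses: more benign than stressful, few mixed-sex assays.
    p = {
        ("male", "benign"): 0.30,
        ("female", "benign"): 0.35,
        ("both", "benign"): 0.08,
        ("male", "stressful"): 0.11,
        ("female", "stressful"): 0.13,
        ("both", "stressful"): 0.03,
    }
    return p


def _design_row(sex: str, environment: str) -> np.ndarray:
    """Row of the sex-by-environment treatment-coded design.

    An undefined environment contributes no stress terms (it is coded
    at the benign reference for the purpose of the true effect).
    """
    x = np.zeros(6)
    x[0] = 1.0
    if sex == "both":
        x[1] = 1.0
    elif sex == "female":
        x[2] = 1.0
    stressed = environment == "stressful"
    if stressed:
        x[3] = 1.0
        if sex == "both":
            x[4] = 1.0
        elif sex == "female":
            x[5] = 1.0
    return x


def _true_effect(config: SimConfig, sex: str, environment: str) -> float:
    if len(config.beta) == 1:
        return config.beta[0]
    return float(_design_row(sex, environment) @ np.asarray(config.beta))


def _mean_shift(theta: float, cv: float) -> float:
    """Relative mean shift delta with SD proportional to the mean.

    Solves theta = delta / sqrt((1 + (1+delta)^2)/2) / cv for delta, so
    that two groups with means mu and mu(1+delta) and SDs cv*mean have
    a population standardized mean difference of exactly theta.
    """
    c = theta * cv
    if abs(c) >= math.sqrt(2.0) - 1e-9:
        raise ConfigurationError(
            f"|theta * cv| = {abs(c):.3f} too large for a CV-proportional "
            "mean-variance relationship"
        )
    return (c * c + c * math.sqrt(4.0 - c * c)) / (2.0 - c * c)


def _draw_groups(
    rng: np.random.Generator, theta_raw: float, n: int, cv: float
) -> tuple[GroupSummary, GroupSummary]:
    """Sample two-group summaries whose population SMD is theta_raw."""
    mu_low = rng.uniform(5.0, 15.0)
    delta = _mean_shift(theta_raw, cv)
    mu_high = mu_low * (1.0 + delta)
    s_low = cv * mu_low
    s_high = cv * abs(mu_high)
    summaries = []
    for mu, s in ((mu_high, s_high), (mu_low, s_low)):
        m_hat = rng.normal(mu, s / math.sqrt(n))
        s_hat = s * math.sqrt(rng.chisquare(n - 1) / (n - 1))
        summaries.append(GroupSummary(m=float(m_hat), s=float(max(s_hat, 1e-12)), n=n))
    return summaries[0], summaries[1]


def _summaries_to_t(high: GroupSummary, low: GroupSummary) -> float:
    df = high.n + low.n - 2
    sp = math.sqrt(((high.n - 1) * high.s ** 2 + (low.n - 1) * low.s ** 2) / df)
    return (high.m - low.m) / (sp * math.sqrt(1.0 / high.n + 1.0 / low.n))


def generate(config: SimConfig) -> SimDataset:
    """Generate a dataset under ``config``; identical seeds give
    identical datasets (one global seed, split per record)."""
    root = np.random.SeedSequence(config.seed)
    struct_rng = np.random.default_rng(root.spawn(1)[0])

    probs = config.moderator_probs or _default_cell_probs()
    cells = list(probs.keys())
    cell_p = np.array([probs[c] for c in cells])
    cell_p = cell_p / cell_p.sum()

    # Level deviations, one draw per label in use.
    u_trait = {
        t: struct_rng.normal(0.0, math.sqrt(config.sigma2_trait))
        for t in config.trait_labels
    }
    u_taxon = {
        t: struct_rng.normal(0.0, math.sqrt(config.sigma2_taxon))
        for t in config.taxon_labels
    }

    records: list[EffectRecord] = []
    truth_rows: list[dict] = []
    rec_index = 0
    for s in range(config.n_studies):
        study_id = f"study_{s + 1:03d}"
        n_eff = int(
            struct_rng.integers(
                config.effects_per_study[0], config.effects_per_study[1] + 1
            )
        )
        taxon = str(struct_rng.choice(config.taxon_labels))
        u_s = struct_rng.normal(0.0, math.sqrt(config.sigma2_study))
        for _ in range(n_eff):
            # per-record stream: split deterministically by record index
            rec_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(1, rec_index))
            )
            trait = str(rec_rng.choice(config.trait_labels))
            sex, env = cells[int(rec_rng.choice(len(cells), p=cell_p))]
            u_e = (
                rec_rng.normal(0.0, math.sqrt(config.sigma2_effect))
                if config.sigma2_effect > 0
                else 0.0
            )
            theta = _true_effect(config, sex, env) + u_s + u_trait[trait] + u_taxon[taxon] + u_e
            n = int(rec_rng.integers(config.group_n_range[0], config.group_n_range[1] + 1))
            cv = float(rec_rng.uniform(*config.cv_range))
            high, low = _draw_groups(rec_rng, theta, n, cv)
            records.append(
                EffectRecord(
                    study_id=study_id,
                    taxon=taxon,
                    trait=trait,
                    fitness_class="direct",
                    sex=sex,
                    environment=env,
                    generations=int(rec_rng.integers(2, 60)),
                    input_kind="summaries",
                    group_high=high,
                    group_low=low,
                    direction=1,
                    negatively_related=False,
                )
            )
            truth_rows.append(
                {
                    "record": rec_index,
                    "study_id": study_id,
                    "trait": trait,
                    "taxon": taxon,
                    "sex": sex,
                    "environment": env,
                    "theta": theta,
                    "u_study": u_s,
                    "u_trait": u_trait[trait],
                    "u_taxon": u_taxon[taxon],
                    "u_effect": u_e,
                }
            )
            rec_index += 1
    return SimDataset(records=records, truth=pd.DataFrame(truth_rows), config=config)


# ---------------------------------------------------------------------------
# A dataset shaped like the motivating synthesis
# ---------------------------------------------------------------------------

#: 22 fitness components: label -> (class, count out of 459).
PAPERLIKE_TRAITS: dict[str, tuple[str, int]] = {
    "female reproductive success": ("direct", 102),
    "offspring viability": ("direct", 56),
    "hatching success": ("direct", 8),
    "extinction rate": ("direct", 6),
    "immunity": ("indirect", 35),
    "lifespan": ("indirect", 30),
    "male mating success": ("indirect", 25),
    "ejaculate quality": ("indirect", 20),
    "sperm competitiveness": ("indirect", 12),
    "parasite load": ("indirect", 10),
    "mutation load": ("indirect", 8),
    "senescence rate": ("indirect", 5),
    "body size": ("ambiguous", 22),
    "male reproductive success": ("ambiguous", 18),
    "early fecundity": ("ambiguous", 16),
    "offspring number": ("ambiguous", 15),
    "mating duration": ("ambiguous", 14),
    "development time": ("ambiguous", 13),
    "body condition": ("ambiguous", 12),
    "fertility": ("ambiguous", 12),
    "male mating latency": ("ambiguous", 11),
    "courtship rate": ("ambiguous", 9),
}

PAPERLIKE_TAXA: dict[str, int] = {
    "flies": 30,
    "beetles": 14,
    "nematodes": 6,
    "mice": 4,
    "mites": 4,
    "crickets": 4,
    "guppies": 3,
}

NEGATIVE_TRAITS = frozenset(
    {"parasite load", "mutation load", "extinction rate", "male mating latency",
     "senescence rate"}
)

PAPERLIKE_N = 459
PAPERLIKE_STUDIES = 65
_SEX_COUNTS = {"male": 189, "female": 219, "both": 51}
_ENV_COUNTS = {"stressful": 92, "benign": 337, "undefined": 30}
_KIND_COUNTS = {"summaries": 354, "t": 70, "F": 25, "chisq": 8, "proportions": 2}
_MANIP_COUNTS = {"enforced monogamy": 241, "sex-ratio manipulation": 218}
_N_MISSING_BIBLIO = 20  # records lacking year / impact factor

#: Default ground truth of the paperlike generator: sex-by-environment
#: fixed effects of realistic size and strongly heterogeneous random
#: levels dominated by between-study and residual variation.
PAPERLIKE_BETA = (0.19, 0.0, 0.11, -0.16, 0.18, 0.26)
PAPERLIKE_SIGMA2 = {"study": 0.60, "trait": 0.007, "taxon": 0.023, "effect": 0.96}


def _exact_label_vector(rng: np.random.Generator, counts: dict[str, int]) -> list[str]:
    labels = [lab for lab, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)
    return labels


def _study_sizes(rng: np.random.Generator, n_studies: int, total: int,
                 max_per_study: int = 30) -> list[int]:
    """Skewed partition of ``total`` effects over studies (each 1..max)."""
    sizes = [1] * n_studies
    remaining = total - n_studies
    while remaining > 0:
        # preferential attachment yields a right-skewed size distribution
        w = np.array(sizes, dtype=float)
        w[w >= max_per_study] = 0.0
        i = int(rng.choice(n_studies, p=w / w.sum()))
        sizes[i] += 1
        remaining -= 1
    return sizes


def generate_paperlike(seed: int) -> SimDataset:
    """A dataset with the marginal shape of the motivating synthesis.

    Exactly 459 effect sizes from 65 studies, 22 fitness components,
    7 taxa, sex counts 189 male / 219 female / 51 both, environment
    counts 92 stressful / 337 benign / 30 undefined, 354 records with
    two-group summaries and the rest reported as test statistics.
    """
    root = np.random.SeedSequence(entropy=seed, spawn_key=(7,))
    rng = np.random.default_rng(root)

    sizes = _study_sizes(rng, PAPERLIKE_STUDIES, PAPERLIKE_N)
    study_ids = [f"study_{i + 1:03d}" for i in range(PAPERLIKE_STUDIES)]
    taxon_of_study = _exact_label_vector(rng, PAPERLIKE_TAXA)

    sex_v = _exact_label_vector(rng, _SEX_COUNTS)
    env_v = _exact_label_vector(rng, _ENV_COUNTS)
    kind_v = _exact_label_vector(rng, _KIND_COUNTS)
    manip_v = _exact_label_vector(rng, _MANIP_COUNTS)
    trait_v = _exact_label_vector(
        rng, {t: c for t, (_, c) in PAPERLIKE_TRAITS.items()}
    )
    missing_biblio = set(
        rng.choice(PAPERLIKE_N, size=_N_MISSING_BIBLIO, replace=False).tolist()
    )

    beta = np.asarray(PAPERLIKE_BETA)
    s2 = PAPERLIKE_SIGMA2
    u_study = {
        sid: rng.normal(0.0, math.sqrt(s2["study"])) for sid in study_ids
    }
    u_trait = {
        t: rng.normal(0.0, math.sqrt(s2["trait"])) for t in PAPERLIKE_TRAITS
    }
    u_taxon = {
        t: rng.normal(0.0, math.sqrt(s2["taxon"])) for t in PAPERLIKE_TAXA
    }
    year_of_study = {
        sid: int(rng.integers(1991, 2017)) for sid in study_ids
    }
    if_of_study = {
        sid: float(np.round(rng.lognormal(math.log(2.8), 0.55), 3))
        for sid in study_ids
    }

    records: list[EffectRecord] = []
    truth_rows: list[dict] = []
    idx = 0
    for s_idx, (sid, n_eff) in enumerate(zip(study_ids, sizes)):
        taxon = taxon_of_study[s_idx]
        for _ in range(n_eff):
            rec_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(7, 1, idx))
            )
            trait = trait_v[idx]
            fitness_class = PAPERLIKE_TRAITS[trait][0]
            sex, env, kind = sex_v[idx], env_v[idx], kind_v[idx]
            negative = trait in NEGATIVE_TRAITS
            u_e = rec_rng.normal(0.0, math.sqrt(s2["effect"]))
            theta = float(_design_row(sex, env) @ beta) + u_study[sid] \
                + u_trait[trait] + u_taxon[taxon] + u_e
            theta_raw = -theta if negative else theta
            n = int(rec_rng.integers(8, 61))
            cv = float(rec_rng.uniform(0.1, 0.45))
            # keep |theta*cv| inside the solvable range of the
            # CV-proportional mean model
            cap = (math.sqrt(2.0) - 0.05) / cv
            theta_used = float(np.clip(theta_raw, -cap, cap))
            high, low = _draw_groups(rec_rng, theta_used, n, cv)

            kwargs: dict = {}
            if kind == "summaries":
                kwargs.update(group_high=high, group_low=low)
            elif kind == "t":
                kwargs.update(
                    statistic_value=float(_summaries_to_t(high, low)),
                    total_n=2 * n,
                )
            elif kind == "F":
                t_stat = _summaries_to_t(high, low)
                kwargs.update(
                    statistic_value=float(t_stat ** 2),
                    total_n=2 * n,
                    direction=1 if t_stat >= 0 else -1,
                )
            elif kind == "chisq":
                t_stat = _summaries_to_t(high, low)
                d = t_stat * math.sqrt(2.0 / n)
                r = d / math.sqrt(d * d + 4.0)
                kwargs.update(
                    statistic_value=float(2 * n * r * r),
                    total_n=2 * n,
                    direction=1 if d >= 0 else -1,
                )
            else:  # proportions
                p_low = 0.5
                logit_high = 1.65 * theta_used
                p_hat = 1.0 / (1.0 + math.exp(-logit_high))
                x_high = int(rec_rng.binomial(n, p_hat))
                x_low = int(rec_rng.binomial(n, p_low))
                kwargs.update(
                    p_high=x_high / n, p_low=x_low / n, total_n=2 * n,
                )

            records.append(
                EffectRecord(
                    study_id=sid,
                    taxon=taxon,
                    trait=trait,
                    fitness_class=fitness_class,
                    sex=sex,
                    environment=env,
                    manipulation=manip_v[idx],
                    generations=int(rec_rng.integers(2, 90)),
                    blind=bool(rec_rng.random() < 0.2),
                    year=None if idx in missing_biblio else year_of_study[sid],
                    impact_factor=None if idx in missing_biblio else if_of_study[sid],
                    input_kind=kind,
                    negatively_related=negative,
                    **kwargs,
                )
            )
            truth_rows.append(
                {
                    "record": idx,
                    "study_id": sid,
                    "trait": trait,
                    "taxon": taxon,
                    "sex": sex,
                    "environment": env,
                    "theta": theta,
                    "u_study": u_study[sid],
                    "u_trait": u_trait[trait],
                    "u_taxon": u_taxon[taxon],
                    "u_effect": u_e,
                }
            )
            idx += 1

    config = SimConfig(
        n_studies=PAPERLIKE_STUDIES,
        effects_per_study=(1, 30),
        trait_labels=tuple(PAPERLIKE_TRAITS),
        taxon_labels=tuple(PAPERLIKE_TAXA),
        beta=PAPERLIKE_BETA,
        sigma2_study=s2["study"],
        sigma2_trait=s2["trait"],
        sigma2_taxon=s2["taxon"],
        sigma2_effect=s2["effect"],
        group_n_range=(8, 60),
        cv_range=(0.1, 0.45),
        seed=seed,
    )
    return SimDataset(records=records, truth=pd.DataFrame(truth_rows), config=config)
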