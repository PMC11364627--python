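"""Synthetic questionnaire populations with known response-type structure.

Respondents are drawn from a finite mixture of the eight published
response-type profiles: each country has a mixing vector (its true
fingerprint), each respondent draws a type from that vector, and each item is
drawn independently from a Gaussian discretised onto the 1..5 Likert grid
whose first two moments are matched to the profile's printed mean/SD.  The
three minor items share one distribution with mean = mean(main means) -
discrimination mean and SD = discrimination SD (no per-minor-item parameters
are published).  Missingness is MCAR.  Country indices with a target Spearman
correlation to a fingerprint component are built by Gaussian-copula blending
of the component's normal scores with independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import load_fixture
from .schema import DEFAULT_SCHEMA, ItemSchema, LIKERT_MAX, LIKERT_MIN

_LEVELS = np.arange(LIKERT_MIN, LIKERT_MAX + 1, dtype=float)
_MEAN_TOL = 0.01


class InfeasibleTargetError(ValueError):
    """Raised when no discretised Gaussian attains the target mean."""

    def __init__(self, target_mean: float, achieved_mean: float):
        self.target_mean = target_mean
        self.achieved_mean = achieved_mean
        super().__init__(
            f"cannot match mean {target_mean:.4g} on the 1..5 grid; "
            f"closest achieved mean {achieved_mean:.4g}"
        )


def discrete_pmf(mu: float, sigma: float) -> np.ndarray:
    """Probability mass on {1..5} of a Gaussian(mu, sigma) binned to the grid.

    Interior levels take the Gaussian mass of their unit bin; the tails fold
    into levels 1 and 5.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    edges = np.array([-np.inf, 1.5, 2.5, 3.5, 4.5, np.inf])
    cdf = stats.norm.cdf(edges, loc=mu, scale=sigma)
    p = np.diff(cdf)
    return p / p.sum()


def _pmf_moments(mu: float, sigma: float) -> tuple[float, float]:
    p = discrete_pmf(mu, sigma)
    m = float((p * _LEVELS).sum())
    v = float((p * (_LEVELS - m) ** 2).sum())
    return m, np.sqrt(v)


def match_discrete_params(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Find (mu, sigma) whose discretised Gaussian matches the target moments.

    The discrete mean is strictly increasing in mu for fixed sigma, so mu is
    found by root bracketing; sigma is then tuned to bring the discrete SD as
    close as possible to ``target_sd`` while re-solving mu.  Matching the
    mean within 0.01 is a hard requirement (means at the grid edge are
    unattainable for wide sigma); the SD is matched on a best-effort basis.
    """
    if not LIKERT_MIN < target_mean < LIKERT_MAX:
        # at the edge the folded mass never quite reaches the endpoint
        achieved = LIKERT_MIN if target_mean <= LIKERT_MIN else LIKERT_MAX
        raise InfeasibleTargetError(target_mean, achieved - np.sign(achieved - 3) * 1e-6)
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")

    def solve_mu(sigma: float) -> float:
        lo, hi = -30.0, 34.0
        return optimize.brentq(
            lambda mu: _pmf_moments(mu, sigma)[0] - target_mean, lo, hi, xtol=1e-10
        )

    def sd_gap(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        mu = solve_mu(sigma)
        return (_pmf_moments(mu, sigma)[1] - target_sd) ** 2

    res = optimize.minimize_scalar(
        sd_gap, bounds=(np.log(0.02), np.log(4.0)), method="bounded",
        options={"xatol": 1e-6},
    )
    sigma = float(np.exp(res.x))
    mu = solve_mu(sigma)
    mean, _sd = _pmf_moments(mu, sigma)
    if abs(mean - target_mean) > _MEAN_TOL:
        raise InfeasibleTargetError(target_mean, mean)
    return mu, sigma


def _default_fingerprints() -> dict[str, np.ndarray]:
    return {"ALL": np.full(8, 1 / 8)}


def _default_n() -> dict[str, int]:
    return {"ALL": 4000}


@dataclass
class GeneratorConfig:
    """Mixture-of-response-types questionnaire generator settings.

    Defaults give a single pooled population of 4000 respondents with the
    eight published profiles equally mixed (500 expected per type), 2%
    MCAR missingness, and a fixed seed.
    """

    profiles: pd.DataFrame = None  # type: ignore[assignment]
    country_fingerprints: dict[str, np.ndarray] = field(
        default_factory=_default_fingerprints
    )
    n_per_country: dict[str, int] = field(default_factory=_default_n)
    missing_rate: float = 0.02
    seed: int = 20200901

    def __post_init__(self) -> None:
        if self.profiles is None:
            self.profiles = load_fixture("table2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        k = len(self.profiles)
        for c, w in self.country_fingerprints.items():
            w = np.asarray(w, dtype=float)
            if len(w) != k or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
                raise ValueError(
                    f"mixing proportions for {c!r} must be a length-{k} "
                    "non-negative vector summing to 1"
                )
            self.country_fingerprints[c] = w
        if set(self.n_per_country) != set(self.country_fingerprints):
            raise ValueError("n_per_country and country_fingerprints disagree")

    @property
    def k(self) -> int:
        return len(self.profiles)


@lru_cache(maxsize=None)
def _matched_item_params(
    profile_key: tuple, main_items: tuple
) -> list[tuple[float, float]]:
    prof = dict(profile_key)
    params = [
        match_discrete_params(prof[f"{item}_mean"], prof[f"{item}_sd"])
        for item in main_items
    ]
    main_mean = float(np.mean([prof[f"{item}_mean"] for item in main_items]))
    minor_mean = main_mean - prof["discrimination_mean"]
    params.append(match_discrete_params(minor_mean, prof["discrimination_sd"]))
    return params


def profile_item_distributions(
    profiles: pd.DataFrame, schema: ItemSchema = DEFAULT_SCHEMA
) -> dict[int, np.ndarray]:
    """Per-type item pmfs: array of shape (8 items, 5 levels) per type.

    Main items get individually matched distributions; the three minor items
    share the matched minor distribution.
    """
    out = {}
    for type_id, row in profiles.iterrows():
        key = tuple(sorted((k, float(v)) for k, v in row.items() if k != "size"))
        params = _matched_item_params(key, schema.main_items)
        pmfs = [discrete_pmf(mu, s) for mu, s in params[:-1]]
        minor_pmf = discrete_pmf(*params[-1])
        pmfs.extend([minor_pmf] * len(schema.minor_items))
        out[int(type_id)] = np.vstack(pmfs)
    return out


def sample_questionnaires(
    config: GeneratorConfig, schema: ItemSchema = DEFAULT_SCHEMA
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a questionnaire population from the configured mixture.

    Returns (matrix, true_labels): the matrix has a ``country`` column plus
    the eight item columns (NaN = missing); true type labels are returned
    for evaluation only and never enter the analysis pipeline.
    """
    rng = np.random.default_rng(config.seed)
    pmfs = profile_item_distributions(config.profiles, schema)
    type_ids = np.asarray(sorted(pmfs), dtype=int)
    countries, labels, items = [], [], []
    for country in sorted(config.country_fingerprints):
        n = config.n_per_country[country]
        w = config.country_fingerprints[country]
        picked = rng.choice(type_ids, size=n, p=w)
        block = np.empty((n, schema.n_items))
        for t in type_ids:
            mask = picked == t
            m = int(mask.sum())
            if m == 0:
                continue
            # inverse-cdf draw per item, vectorised over respondents
            u = rng.random((m, schema.n_items))
            cum = np.cumsum(pmfs[t], axis=1)  # (items, levels)
            block[mask] = 1 + (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        countries.append(np.full(n, country))
        labels.append(picked)
        items.append(block)
    X = np.vstack(items)
    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = np.where(mask, np.nan, X)
    df = pd.DataFrame(X, columns=list(schema.items))
    df.insert(0, "country", np.concatenate(countries))
    return df, np.concatenate(labels)


def sample_index(
    component: pd.Series, target_rho: float, seed: int = 0
) -> pd.Series:
    """Per-country index values with a target Spearman correlation.

    The component's average ranks are converted to normal scores and blended
    with independent Gaussian noise using Pearson weight 2*sin(pi*rho/6), the
    inverse of the Gaussian-copula rank-correlation map, so the expected
    Spearman correlation equals ``target_rho``.  |target_rho| = 1 yields an
    exact monotone (or antitone) transform.
    """
    x = component.to_numpy(dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 countries")
    if np.ptp(x) == 0:
        raise ValueError("degenerate component: all values equal")
    if not -1 <= target_rho <= 1:
        raise ValueError("target_rho must lie in [-1, 1]")
    n = len(x)
    ranks = stats.rankdata(x)
    u = stats.norm.ppf(ranks / (n + 1))
    if abs(target_rho) == 1:
        z = np.sign(target_rho) * u
    else:
        rho_p = 2 * np.sin(np.pi * target_rho / 6)
        rng = np.random.default_rng(seed)
        z = rho_p * u + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
    return pd.Series(z, index=component.index, name=component.name)
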