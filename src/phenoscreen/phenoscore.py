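"""Reference-profile construction and correlation phenoscoring.

The phenoscore of a well is the Pearson correlation between its motion-index
series and an archetype reference profile, so it lives in [-1, +1]: positive
values mean the well phenocopies the archetype.  The reference is the
average of a subset of replicate positive-control wells chosen by simulated
annealing to be maximally self-consistent while maximally dissimilar from
vehicle (DMSO) wells.  Significance cutoffs come from scoring simulated null
wells against the frozen reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError
from .profile_core import BehavioralProfile


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing hyperparameters for reference selection."""

    subset_size: int = 12
    n_iterations: int = 20_000
    initial_temperature: float | None = None  # None: SD of J over 100 random subsets
    cooling_rate: float = 0.995
    lambda_dmso: float = 1.0  # weight of the distance-to-DMSO term
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset_size < 1 or self.n_iterations < 1:
            raise InvalidInputError("subset_size and n_iterations must be >= 1")
        if not 0.0 < self.cooling_rate < 1.0:
            raise InvalidInputError("cooling_rate must be in (0, 1)")


@dataclass
class ReferenceProfile:
    """Averaged archetype profile plus provenance of its selection."""

    profile: np.ndarray
    member_ids: tuple[str, ...]
    objective_value: float
    anneal_config: AnnealConfig | None = None

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.ndim != 1 or self.profile.size < 2:
            raise InvalidInputError("reference profile must be a 1-D series")
        if np.std(self.profile) == 0:
            raise DegenerateInputError("reference profile has zero variance")


@dataclass(frozen=True)
class PhenoscoreResult:
    well_id: str
    phenoscore: float
    degenerate: bool = False


@dataclass(frozen=True)
class CutoffResult:
    """Simulated-null significance cutoffs (upper quantiles of null scores)."""

    cutoffs: dict[float, float]
    null_sample_size: int
    procedure: str = "null wells scored against frozen reference"

    @property
    def cutoff_1pct(self) -> float:
        return self.cutoffs[0.01]

    @property
    def cutoff_5pct(self) -> float:
        return self.cutoffs[0.05]


@dataclass(frozen=True)
class QualityStats:
    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    z_factor: float
    ks_statistic: float
    ks_pvalue: float
    z_factor_defined: bool = True


def _as_series(profile) -> tuple[np.ndarray, str]:
    if isinstance(profile, BehavioralProfile):
        return profile.mi, profile.well_id
    if isinstance(profile, ReferenceProfile):
        return profile.profile, "reference"
    return np.asarray(profile, dtype=float), ""


def _align(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # off-by-one lengths happen at battery edges; anything larger is a bug
    if abs(x.size - y.size) > 1:
        raise InvalidInputError(f"profile length mismatch: {x.size} vs {y.size}")
    n = min(x.size, y.size)
    return x[:n], y[:n]


def phenoscore(profile, reference) -> PhenoscoreResult:
    """Pearson correlation between a well's MI series and the reference.

    Equivalently 1 minus the correlation distance.  A zero-variance
    (fully immobilized) well scores 0 with the degenerate flag set; a
    zero-variance reference is an error.
    """
    x, well_id = _as_series(profile)
    ref, _ = _as_series(reference)
    x, ref = _align(x, ref)
    if np.std(ref) == 0:
        raise DegenerateInputError("reference has zero variance")
    if np.std(x) == 0:
        return PhenoscoreResult(well_id=well_id, phenoscore=0.0, degenerate=True)
    r = float(np.corrcoef(x, ref)[0, 1])
    return PhenoscoreResult(well_id=well_id, phenoscore=r, degenerate=False)


def score_profiles(profiles: Sequence, reference) -> list[PhenoscoreResult]:
    return [phenoscore(p, reference) for p in profiles]


# --------------------------------------------------------------------------
# reference selection
# --------------------------------------------------------------------------

def _profile_matrix(profiles) -> tuple[np.ndarray, list[str]]:
    series, ids = [], []
    for i, p in enumerate(profiles):
        x, wid = _as_series(p)
        series.append(x)
        ids.append(wid or str(i))
    n = min(s.size for s in series)
    if any(s.size - n > 1 for s in series):
        raise InvalidInputError("candidate profiles differ in length by more than 1 sample")
    return np.stack([s[:n] for s in series]), ids


def subset_objective(
    within_corr: np.ndarray, to_dmso_corr: np.ndarray, subset: Sequence[int], lambda_dmso: float
) -> float:
    """J(S) = mean pairwise correlation within S minus lambda times the mean
    correlation between members of S and the DMSO wells."""
    idx = np.asarray(subset)
    sub = within_corr[np.ix_(idx, idx)]
    k = idx.size
    within = (sub.sum() - np.trace(sub)) / (k * (k - 1)) if k > 1 else 1.0
    return float(within - lambda_dmso * to_dmso_corr[idx].mean())


def select_reference(
    candidates: Sequence,
    dmso_profiles: Sequence,
    config: AnnealConfig | None = None,
) -> ReferenceProfile:
    """Choose the most consistent, most-DMSO-distant replicate subset.

    Maximizes J(S) over size-``subset_size`` subsets by simulated annealing
    with swap-one-member proposals, Metropolis acceptance and geometric
    cooling, then averages the selected members into the reference profile.
    The best subset ever visited is returned, so the result never falls
    below the proposal chain's own optimum.
    """
    config = config or AnnealConfig()
    x, ids = _profile_matrix(candidates)
    n = x.shape[0]
    k = config.subset_size
    if n < k:
        raise InvalidInputError(f"need >= {k} candidates, got {n}")
    if len(dmso_profiles) < 1:
        raise InvalidInputError("need at least one DMSO profile")
    d, _ = _profile_matrix(dmso_profiles)
    m = min(x.shape[1], d.shape[1])
    if abs(x.shape[1] - d.shape[1]) > 1:
        raise InvalidInputError("candidate and DMSO profiles differ in length by more than 1 sample")
    x, d = x[:, :m], d[:, :m]
    if np.any(np.std(x, axis=1) == 0) or np.any(np.std(d, axis=1) == 0):
        raise DegenerateInputError("zero-variance profile among candidates or DMSO wells")

    full = np.corrcoef(np.vstack([x, d]))
    within = full[:n, :n]
    to_dmso = full[:n, n:].mean(axis=1)  # mean corr of each candidate to DMSO wells

    rng = np.random.default_rng(config.seed)
    obj = lambda s: subset_objective(within, to_dmso, s, config.lambda_dmso)

    if n == k:
        subset = list(range(n))
        return _finalize_reference(x, ids, subset, obj(subset), config)

    temp = config.initial_temperature
    if temp is None:
        samples = [obj(rng.choice(n, size=k, replace=False)) for _ in range(100)]
        temp = float(np.std(samples)) or 1e-3

    current = list(rng.choice(n, size=k, replace=False))
    current_j = obj(current)
    best, best_j = list(current), current_j
    outside = [i for i in range(n) if i not in set(current)]
    for _ in range(config.n_iterations):
        i_in = rng.integers(k)
        i_out = rng.integers(len(outside))
        proposal = list(current)
        proposal[i_in], swapped_out = outside[i_out], proposal[i_in]
        prop_j = obj(proposal)
        delta = prop_j - current_j
        if delta >= 0 or rng.random() < math.exp(delta / max(temp, 1e-300)):
            current, current_j = proposal, prop_j
            outside[i_out] = swapped_out
            if current_j > best_j:
                best, best_j = list(current), current_j
        temp *= config.cooling_rate
    return _finalize_reference(x, ids, best, best_j, config)


def _finalize_reference(x, ids, subset, j, config) -> ReferenceProfile:
    subset = sorted(subset)
    return ReferenceProfile(
        profile=x[subset].mean(axis=0),
        member_ids=tuple(ids[i] for i in subset),
        objective_value=float(j),
        anneal_config=config,
    )


def exhaustive_reference(
    candidates: Sequence, dmso_profiles: Sequence, subset_size: int, lambda_dmso: float = 1.0
) -> ReferenceProfile:
    """Exact optimum by enumerating every size-k subset (small inputs only)."""
    x, ids = _profile_matrix(candidates)
    d, _ = _profile_matrix(dmso_profiles)
    m = min(x.shape[1], d.shape[1])
    full = np.corrcoef(np.vstack([x[:, :m], d[:, :m]]))
    n = x.shape[0]
    within, to_dmso = full[:n, :n], full[:n, n:].mean(axis=1)
    best, best_j = None, -np.inf
    for subset in itertools.combinations(range(n), subset_size):
        j = subset_objective(within, to_dmso, subset, lambda_dmso)
        if j > best_j:
            best, best_j = subset, j
    return _finalize_reference(x[:, :m], ids, list(best), best_j, None)


# --------------------------------------------------------------------------
# simulated cutoffs and assay quality
# --------------------------------------------------------------------------

def simulate_cutoffs(
    null_generator: Callable,
    reference: ReferenceProfile | np.ndarray,
    alpha_levels: Sequence[float] = (0.01, 0.05),
    n_sim: int = 10_000,
    seed: int = 0,
) -> CutoffResult:
    """Significance cutoffs as upper quantiles of a simulated null.

    ``null_generator(rng)`` returns either a null-well profile (scored
    against the reference) or directly a null phenoscore.  Each alpha maps to
    the (1 - alpha) quantile of the null distribution, so smaller alpha gives
    a larger cutoff.
    """
    if n_sim < 1000:
        raise InvalidInputError("n_sim must be >= 1000 for stable quantiles")
    if any(not 0.0 < a <= 1.0 for a in alpha_levels):
        raise InvalidInputError("alpha levels must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_sim)
    for i in range(n_sim):
        draw = null_generator(rng)
        if isinstance(draw, (int, float, np.floating)):
            scores[i] = float(draw)
        else:
            scores[i] = phenoscore(draw, reference).phenoscore
    if np.std(scores) == 0:
        raise DegenerateInputError("degenerate null: all simulated scores identical")
    cutoffs = {float(a): float(np.quantile(scores, 1.0 - a)) for a in alpha_levels}
    return CutoffResult(cutoffs=cutoffs, null_sample_size=n_sim)


def quality_stats(pos_scores, neg_scores) -> QualityStats:
    """Group means/SDs, the screening-window Z-factor and a two-sample KS test.

    Z-factor = 1 - 3 (sd_pos + sd_neg) / |mu_pos - mu_neg|; identical group
    means leave it undefined (reported as -inf with the flag cleared).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise InvalidInputError("need >= 2 scores per arm")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    ks = stats.ks_2samp(pos, neg)
    if mu_p == mu_n:
        return QualityStats(mu_p, sd_p, mu_n, sd_n, float("-inf"),
                            float(ks.statistic), float(ks.pvalue), z_factor_defined=False)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return QualityStats(mu_p, sd_p, mu_n, sd_n, float(z), float(ks.statistic), float(ks.pvalue))
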