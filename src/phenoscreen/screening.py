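"""Hit calling, toxicity calls, dose-response fitting and efficacy windows.

A screen table is a pandas DataFrame with one row per well:
``compound_id, well_id, phenoscore, immobilization_index, total_mi,
concentration_uM, call``.  Compounds are ranked by mean phenoscore over
replicate wells; the top-k become hits, strongly immobilized low-scoring
compounds become toxic, the rest inactive; vehicle wells are controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InvalidInputError, MissingDataError
from .profile_core import BehavioralProfile, response_magnitudes

SCREEN_COLUMNS = [
    "compound_id", "well_id", "phenoscore", "immobilization_index",
    "total_mi", "concentration_uM", "call",
]

CONTROL_TREATMENT = "DMSO"
DEFAULT_K_HITS = 125
DEFAULT_TOXIC_IMMOBILIZATION = 0.9


@dataclass(frozen=True)
class DoseResponseFit:
    ec50_uM: float
    hill: float
    top: float
    bottom: float
    rmse: float
    converged: bool


@dataclass(frozen=True)
class EfficacyWindow:
    """Contiguous run of concentrations with strong phenocopy scores."""

    concentrations: tuple[float, ...]
    strengths: tuple[str, ...]          # 'strong' / 'weak' per concentration
    window: tuple[float, ...]           # longest contiguous strong run

    @property
    def width(self) -> int:
        return len(self.window)


def dmso_violet_median(dmso_profiles: Sequence[BehavioralProfile], *, tail_s: float = 1.0) -> float:
    """Median violet-response magnitude of the vehicle wells."""
    mags = [response_magnitudes(p, tail_s=tail_s).violet_mag for p in dmso_profiles]
    mags = [m for m in mags if m is not None]
    if not mags:
        raise InvalidInputError("no violet responses among the DMSO profiles")
    med = float(np.median(mags))
    if med <= 0:
        raise InvalidInputError("DMSO reference violet magnitude must be > 0")
    return med


def immobilization_index(
    profile: BehavioralProfile, dmso_violet_magnitude: float, *, tail_s: float = 1.0
) -> float:
    """Suppression of the light-evoked response relative to vehicle, in [0, 1].

    1 - clip(violet_mag / median DMSO violet_mag, 0, 1): 0 means vehicle-like
    light response, 1 fully immobilized.
    """
    if dmso_violet_magnitude <= 0:
        raise InvalidInputError("DMSO reference violet magnitude must be > 0")
    mag = response_magnitudes(profile, tail_s=tail_s).violet_mag
    if mag is None:
        raise InvalidInputError("profile's battery has no violet events")
    return float(1.0 - np.clip(mag / dmso_violet_magnitude, 0.0, 1.0))


def build_screen_table(
    profiles: Sequence[BehavioralProfile],
    scores,
    *,
    tail_s: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-well screen table from profiles and their phenoscores."""
    dmso = [p for p in profiles if p.treatment == CONTROL_TREATMENT]
    ref_violet = dmso_violet_median(dmso, tail_s=tail_s) if dmso else None
    score_of = {s.well_id: s.phenoscore for s in scores}
    rows = []
    for p in profiles:
        imm = immobilization_index(p, ref_violet, tail_s=tail_s) if ref_violet else np.nan
        rows.append({
            "compound_id": p.treatment,
            "well_id": p.well_id,
            "phenoscore": score_of[p.well_id],
            "immobilization_index": imm,
            "total_mi": float(p.mi.sum()),
            "concentration_uM": p.concentration_uM,
            "call": "control" if p.treatment == CONTROL_TREATMENT else "",
        })
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)


def compound_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-compound screen score: mean phenoscore (and immobilization) over
    replicate wells, vehicle wells excluded."""
    t = table[table["compound_id"] != CONTROL_TREATMENT]
    return (
        t.groupby("compound_id", as_index=False)
        .agg(phenoscore=("phenoscore", "mean"),
             immobilization_index=("immobilization_index", "mean"))
    )


def rank_and_call(
    table: pd.DataFrame,
    k_hits: int = DEFAULT_K_HITS,
    *,
    toxic_immobilization: float = DEFAULT_TOXIC_IMMOBILIZATION,
    hit_floor: float | None = None,
) -> pd.DataFrame:
    """Rank compounds by phenoscore and call hit / toxic / inactive / control.

    The top ``k_hits`` compounds by mean phenoscore (descending; ties broken
    by lexicographic compound_id so the rule is deterministic) are hits.
    Non-hit compounds with mean immobilization >= ``toxic_immobilization``
    and phenoscore below the hit floor (default: the last hit's score) are
    toxic; the rest are inactive.  Vehicle wells are controls.
    """
    if k_hits <= 0:
        raise InvalidInputError("k_hits must be > 0")
    summary = compound_scores(table)
    if k_hits > len(summary):
        raise InvalidInputError(f"k_hits={k_hits} exceeds {len(summary)} compounds")
    ranked = summary.sort_values(
        ["phenoscore", "compound_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    hits = set(ranked.loc[: k_hits - 1, "compound_id"])
    floor = hit_floor if hit_floor is not None else float(ranked.loc[k_hits - 1, "phenoscore"])

    def call_of(row) -> str:
        if row["compound_id"] in hits:
            return "hit"
        if row["immobilization_index"] >= toxic_immobilization and row["phenoscore"] < floor:
            return "toxic"
        return "inactive"

    calls = {r["compound_id"]: call_of(r) for _, r in ranked.iterrows()}
    out = table.copy()
    out["call"] = out["call"].astype(object)
    mask = out["compound_id"] != CONTROL_TREATMENT
    out.loc[mask, "call"] = out.loc[mask, "compound_id"].map(calls)
    out.loc[~mask, "call"] = "control"
    return out


# --------------------------------------------------------------------------
# dose-response
# --------------------------------------------------------------------------

def _four_pl(logc, log_ec50, hill, bottom, top):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


def fit_dose_response(concentrations_uM, responses) -> DoseResponseFit:
    """Least-squares 4-parameter logistic fit on log10 concentration.

    Multi-start initialization over the tested ladder; EC50 is constrained to
    the tested span times [0.1, 10].  Non-convergence and flat responses
    return ``converged=False`` with diagnostics rather than raising.
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if conc.shape != y.shape or conc.ndim != 1:
        raise InvalidInputError("concentrations and responses must be equal-length 1-D")
    if np.any(conc <= 0):
        raise InvalidInputError("concentrations must be > 0")
    distinct = np.unique(conc)
    if distinct.size < 4:
        raise InvalidInputError("need >= 4 distinct concentrations")
    logc = np.log10(conc)
    lo, hi = np.log10(distinct[0] * 0.1), np.log10(distinct[-1] * 10.0)
    span = float(y.max() - y.min())
    if span < 1e-12:  # perfectly flat: EC50 unidentifiable
        return DoseResponseFit(float("nan"), 0.0, float(y.mean()), float(y.mean()), 0.0, False)
    bounds = (
        [lo, 0.01, y.min() - span, y.min() - span],
        [hi, 20.0, y.max() + span, y.max() + span],
    )
    best, best_sse = None, np.inf
    inits = [(np.log10(c0), h0) for c0 in distinct for h0 in (1.0, 2.0)]
    for log_c0, h0 in inits:
        p0 = [np.clip(log_c0, lo, hi), h0, float(y.min()), float(y.max())]
        try:
            popt, _ = curve_fit(_four_pl, logc, y, p0=p0, bounds=bounds, maxfev=10_000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((_four_pl(logc, *popt) - y) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        return DoseResponseFit(float("nan"), float("nan"), float("nan"), float("nan"),
                               float("nan"), False)
    log_ec50, hill, bottom, top = (float(v) for v in best)
    rmse = float(np.sqrt(best_sse / y.size))
    converged = np.isfinite(best).all() and abs(top - bottom) > 1e-8 * max(1.0, abs(top))
    return DoseResponseFit(10.0 ** log_ec50, hill, top, bottom, rmse, bool(converged))


def efficacy_window(dose_table: pd.DataFrame, strong_cutoff: float) -> EfficacyWindow:
    """Classify each ladder concentration strong/weak and find the window.

    A concentration is strong when its mean phenoscore reaches
    ``strong_cutoff`` (by convention the 5% simulated cutoff); the window is
    the longest contiguous strong run on the ascending ladder (first run on
    ties).
    """
    if len(dose_table) == 0:
        raise InvalidInputError("empty dose table")
    means = (
        dose_table.groupby("concentration_uM")["phenoscore"].mean().sort_index()
    )
    concs = tuple(float(c) for c in means.index)
    strong = means.to_numpy() >= strong_cutoff
    strengths = tuple("strong" if s else "weak" for s in strong)
    best_start, best_len, run_start = 0, 0, None
    for i, s in enumerate(list(strong) + [False]):
        if s and run_start is None:
            run_start = i
        elif not s and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    window = concs[best_start: best_start + best_len]
    return EfficacyWindow(concentrations=concs, strengths=strengths, window=window)


def reproducibility_rate(
    primary_hits: Sequence[str],
    retest_results: pd.DataFrame,
    strong_cutoff: float,
) -> float:
    """Fraction of primary hits with >= 1 retest concentration scoring strong.

    ``retest_results`` holds per-well rows (compound_id, concentration_uM,
    phenoscore); a compound reproduces when its mean phenoscore at any
    concentration reaches the cutoff.  Hits missing from the retest table are
    an error (listed).
    """
    hits = [str(h) for h in primary_hits]
    if not hits:
        raise InvalidInputError("no primary hits given")
    present = set(retest_results["compound_id"].astype(str))
    missing = [h for h in hits if h not in present]
    if missing:
        raise MissingDataError(f"primary hits without retest rows: {missing}")
    per_conc = (
        retest_results.groupby(["compound_id", "concentration_uM"])["phenoscore"]
        .mean()
        .reset_index()
    )
    passed = {
        cid
        for cid, grp in per_conc.groupby("compound_id")
        if (grp["phenoscore"] >= strong_cutoff).any()
    }
    return sum(h in passed for h in hits) / len(hits)
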