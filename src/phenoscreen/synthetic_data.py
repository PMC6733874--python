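"""Seeded synthetic plates, screens, dose series, frame stacks and compound
libraries with the statistical structure the analysis assumes.

The generative behavioral model is

    MI(t) = m_w * [ g_b(c) * b(t) + g_a(c) * A(t) + g_v(c) * V(t) ] + eps(t),
    truncated at 0,

where b(t) is smoothed positive baseline noise, A(t) is a sum of
alpha-function startle kernels at the acoustic tap onsets (each event with
per-well latency and lognormal amplitude jitter — the dominant biological
variability of startle responses), V(t) is a sum of sustained boxcars with
an onset transient at the light pulses, eps is white measurement noise, and
m_w ~ lognormal(0, well_noise_sd) is a per-well sensitivity multiplier.  Concentration-dependent gains interpolate between
vehicle behavior (gain 1) and the phenotype class's asymptotic gains along a
Hill dose law, optionally with a descending high-concentration arm to
produce bell-shaped efficacy windows.

All constants live in :data:`DEFAULT_CONFIG`/:data:`CLASS_DEFAULTS`; the
defaults are calibrated so that the full pipeline (reference selection then
correlation scoring) yields positive-control phenoscores of about
0.71 +/- 0.11 and vehicle-control phenoscores of about 0.20 +/- 0.05.

Randomness contract: every public generator takes one root seed and derives
hierarchical per-well substreams from it, so adding wells never perturbs
existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .chem import CompoundRecord
from .errors import InvalidInputError
from .profile_core import BehavioralProfile, FrameStack, StimulusEvent, StimulusTrain


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeClassParams:
    """Asymptotic (full-effect) gains and noise levels for one phenotype class.

    ``latency_jitter_s``/``amp_jitter`` set the per-event startle latency SD
    (s) and lognormal amplitude SD at full effect — paradoxical startle under
    sedation is far more variable than the vehicle response.
    """

    name: str
    baseline_gain: float
    acoustic_gain: float
    violet_gain: float
    well_noise_sd: float
    measurement_noise_sd: float
    latency_jitter_s: float = 0.15
    amp_jitter: float = 0.25

    def __post_init__(self) -> None:
        if min(self.baseline_gain, self.acoustic_gain, self.violet_gain) < 0:
            raise InvalidInputError("gains must be >= 0")
        if min(self.well_noise_sd, self.measurement_noise_sd,
               self.latency_jitter_s, self.amp_jitter) < 0:
            raise InvalidInputError("noise SDs must be >= 0")


@dataclass(frozen=True)
class DoseLaw:
    """Hill dose law, optionally with a descending high-concentration arm.

    The effect fraction at concentration c (uM) is
    f(c) = bottom + (top - bottom) / (1 + (ec50/c)^hill), multiplied, when a
    descending arm is present, by 1 / (1 + (c/ec50_hi)^hill_hi) — giving the
    bell shape behind narrow efficacy windows.
    """

    ec50_uM: float
    hill: float = 2.0
    top: float = 1.0
    bottom: float = 0.0
    ec50_hi_uM: float | None = None
    hill_hi: float = 2.0

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0 or self.hill <= 0:
            raise InvalidInputError("ec50 and hill must be > 0")
        if self.ec50_hi_uM is not None and self.ec50_hi_uM <= self.ec50_uM:
            raise InvalidInputError("descending arm requires ec50_hi > ec50")

    def response(self, concentration_uM: float) -> float:
        c = float(concentration_uM)
        if c < 0:
            raise InvalidInputError("concentration must be >= 0")
        if c == 0.0:
            return self.bottom
        f = self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50_uM / c) ** self.hill)
        if self.ec50_hi_uM is not None:
            f *= 1.0 / (1.0 + (c / self.ec50_hi_uM) ** self.hill_hi)
        return f


@dataclass(frozen=True)
class GeneratorConfig:
    """All constants of the generative model, in one versioned place.

    Amplitudes are in arbitrary MI units on the same scale as the unit
    baseline level; times in seconds.
    """

    sample_rate_hz: float = 25.0
    baseline_level: float = 2.0
    baseline_jitter: float = 0.25      # relative SD of smoothed baseline noise
    baseline_smooth_s: float = 1.0     # gaussian smoothing sigma of b(t)
    acoustic_amp: float = 1.9          # vehicle startle kernel peak
    acoustic_tau_s: float = 0.5        # alpha-kernel time constant
    vehicle_latency_jitter_s: float = 0.15   # zero-effect startle latency SD
    vehicle_amp_jitter: float = 0.25   # zero-effect lognormal amplitude SD
    violet_amp: float = 1.5            # vehicle sustained light response
    violet_transient_amp: float = 1.0  # relative onset transient
    violet_transient_tau_s: float = 0.7
    reference_concentration_uM: float = 6.25
    screening_concentration_uM: float = 10.0
    n_fish: int = 8


DEFAULT_CONFIG = GeneratorConfig()

#: Reference dose law for the archetypal sedative+eASR compound (EC50 1 uM).
ETOMIDATE_LIKE_DOSE_LAW = DoseLaw(ec50_uM=1.0, hill=2.0)

CLASS_DEFAULTS: dict[str, PhenotypeClassParams] = {
    "dmso": PhenotypeClassParams("dmso", 1.0, 1.0, 1.0, 0.08, 0.92, 0.05, 0.10),
    "inactive": PhenotypeClassParams("inactive", 1.0, 1.0, 1.0, 0.08, 0.92, 0.05, 0.10),
    "etomidate_like": PhenotypeClassParams(
        "etomidate_like", 0.35, 5.0, 0.12, 0.50, 1.35, 0.25, 0.40
    ),
    "toxic": PhenotypeClassParams("toxic", 0.0, 0.0, 0.0, 0.0, 0.02, 0.0, 0.0),
    "stimulant": PhenotypeClassParams("stimulant", 2.0, 1.5, 1.2, 0.25, 1.0),
}


def _seed_seq(seed, *key: int) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(entropy=seed.entropy, spawn_key=tuple(key))
    return np.random.SeedSequence(entropy=[int(seed), *key])


# --------------------------------------------------------------------------
# stimulus battery
# --------------------------------------------------------------------------

def generate_battery(
    n_acoustic: int = 6,
    n_violet: int = 3,
    *,
    acoustic_spacing_s: float = 10.0,
    acoustic_duration_s: float = 0.07,
    violet_on_s: float = 10.0,
    violet_off_s: float = 10.0,
    assay_duration_s: float = 60.0,
) -> StimulusTrain:
    """Default two-assay battery.

    Assay 1 (60 s): repeated low-amplitude acoustic taps at 10 s spacing.
    Assay 2 (60 s): sustained violet light pulses, 10 s on / 10 s off.
    """
    if n_acoustic < 1 or n_violet < 1:
        raise InvalidInputError("battery needs at least one event of each assay")
    events = [
        StimulusEvent("acoustic_low", 5.0 + i * acoustic_spacing_s, acoustic_duration_s)
        for i in range(n_acoustic)
    ]
    if events[-1].offset_s > assay_duration_s:
        raise InvalidInputError("acoustic train does not fit in assay 1")
    for j in range(n_violet):
        onset = assay_duration_s + j * (violet_on_s + violet_off_s)
        events.append(StimulusEvent("violet", onset, violet_on_s))
    total = 2 * assay_duration_s
    if events[-1].offset_s > total:
        raise InvalidInputError("violet train does not fit in assay 2")
    return StimulusTrain(tuple(events), total_duration_s=total, assay_starts=(0.0, assay_duration_s))


# --------------------------------------------------------------------------
# well profiles
# --------------------------------------------------------------------------

def _acoustic_template(
    battery: StimulusTrain,
    config: GeneratorConfig,
    n: int,
    rng: np.random.Generator | None = None,
    latency_jitter_s: float = 0.0,
    amp_jitter: float = 0.0,
) -> np.ndarray:
    """Sum of alpha-function startle kernels at the tap onsets.

    With an rng, each event gets per-well latency jitter and lognormal
    amplitude jitter — the dominant well-to-well variability of startle
    responses; without one, the noise-free mean response.
    """
    times = (np.arange(n) + 1.0) / config.sample_rate_hz
    acoustic = np.zeros(n)
    tau = config.acoustic_tau_s
    for e in battery.acoustic_events:
        onset, amp = e.onset_s, e.amplitude
        if rng is not None:
            onset += rng.normal(0.0, latency_jitter_s)
            amp *= math.exp(rng.normal(0.0, amp_jitter))
        dt = times - onset
        mask = dt >= 0
        u = dt[mask] / tau
        acoustic[mask] += amp * u * np.exp(1.0 - u)
    return acoustic


def _violet_template(battery: StimulusTrain, config: GeneratorConfig, n: int) -> np.ndarray:
    """Sustained boxcar with an onset transient at each light pulse."""
    times = (np.arange(n) + 1.0) / config.sample_rate_hz
    violet = np.zeros(n)
    for e in battery.violet_events:
        dt = times - e.onset_s
        on = (dt >= 0) & (times < e.offset_s)
        violet[on] += e.amplitude * (
            1.0 + config.violet_transient_amp * np.exp(-dt[on] / config.violet_transient_tau_s)
        )
    return violet


def generate_well_profile(
    class_params: PhenotypeClassParams,
    dose_law: DoseLaw | None,
    concentration_uM: float,
    battery: StimulusTrain,
    seed,
    *,
    config: GeneratorConfig = DEFAULT_CONFIG,
    noise_free: bool = False,
    well_id: str = "",
    plate_id: str = "",
    treatment: str | None = None,
) -> BehavioralProfile:
    """One well's MI series under a phenotype class, dose law and concentration.

    ``seed`` is an int or SeedSequence; identical seeds and parameters give
    bit-identical profiles.  ``noise_free`` drops the well multiplier,
    baseline jitter and measurement noise (deterministic mean response).
    """
    if concentration_uM < 0:
        raise InvalidInputError("concentration must be >= 0")
    rng = np.random.default_rng(_seed_seq(seed))
    p = class_params
    f = dose_law.response(concentration_uM) if dose_law is not None else 1.0
    g_b = 1.0 + f * (p.baseline_gain - 1.0)
    g_a = 1.0 + f * (p.acoustic_gain - 1.0)
    g_v = 1.0 + f * (p.violet_gain - 1.0)

    n = int(round(battery.total_duration_s * config.sample_rate_hz))
    violet = _violet_template(battery, config, n)
    if noise_free:
        acoustic = _acoustic_template(battery, config, n)
        base = np.full(n, config.baseline_level)
        mi = g_b * base + g_a * config.acoustic_amp * acoustic + g_v * config.violet_amp * violet
    else:
        # startle variability interpolates toward the class value with dose
        lat = config.vehicle_latency_jitter_s + f * (
            p.latency_jitter_s - config.vehicle_latency_jitter_s
        )
        aj = config.vehicle_amp_jitter + f * (p.amp_jitter - config.vehicle_amp_jitter)
        acoustic = _acoustic_template(battery, config, n, rng, lat, aj)
        sigma_samples = config.baseline_smooth_s * config.sample_rate_hz
        smooth = gaussian_filter1d(rng.standard_normal(n), sigma_samples, mode="reflect")
        smooth *= config.baseline_jitter / max(np.std(smooth), 1e-12)
        base = config.baseline_level * np.clip(1.0 + smooth, 0.0, None)
        # group-size noise scaling: measurement noise averages over n_fish larvae
        meas_sd = p.measurement_noise_sd * math.sqrt(8.0 / config.n_fish)
        well_mult = math.exp(rng.normal(0.0, p.well_noise_sd)) if p.well_noise_sd > 0 else 1.0
        signal = g_b * base + g_a * config.acoustic_amp * acoustic + g_v * config.violet_amp * violet
        mi = well_mult * signal + rng.normal(0.0, meas_sd, n)
    mi = np.clip(mi, 0.0, None)
    return BehavioralProfile(
        mi=mi,
        stimulus_train=battery,
        sample_rate_hz=config.sample_rate_hz,
        well_id=well_id,
        plate_id=plate_id,
        treatment=treatment if treatment is not None else p.name,
        concentration_uM=concentration_uM,
        n_fish=config.n_fish,
    )


def generate_control_plates(
    n_pos: int,
    n_neg: int,
    seed,
    *,
    battery: StimulusTrain | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> list[BehavioralProfile]:
    """Positive (etomidate-like at the reference concentration) and DMSO wells.

    Positives come first; the ground-truth class is recorded in ``treatment``.
    """
    if n_pos < 0 or n_neg < 0:
        raise InvalidInputError("well counts must be >= 0")
    battery = battery or generate_battery()
    wells: list[BehavioralProfile] = []
    for i in range(n_pos):
        wells.append(
            generate_well_profile(
                CLASS_DEFAULTS["etomidate_like"],
                ETOMIDATE_LIKE_DOSE_LAW,
                config.reference_concentration_uM,
                battery,
                _seed_seq(seed, 0, i),
                config=config,
                well_id=f"POS{i:04d}",
                treatment="etomidate_like",
            )
        )
    for i in range(n_neg):
        wells.append(
            generate_well_profile(
                CLASS_DEFAULTS["dmso"],
                None,
                0.0,
                battery,
                _seed_seq(seed, 1, i),
                config=config,
                well_id=f"NEG{i:04d}",
                treatment="DMSO",
            )
        )
    return wells


# --------------------------------------------------------------------------
# screens and libraries
# --------------------------------------------------------------------------

@dataclass
class SyntheticLibrary:
    """Compound records plus the generator's ground truth per compound."""

    compounds: list[CompoundRecord]
    truth: pd.DataFrame  # compound_id, phenotype, cluster, ec50_uM

    def __post_init__(self) -> None:
        ids = {c.compound_id for c in self.compounds}
        if set(self.truth["compound_id"]) != ids:
            raise InvalidInputError("truth table must cover every compound exactly")

    def dose_law_for(self, compound_id: str) -> DoseLaw | None:
        row = self.truth.loc[self.truth["compound_id"] == compound_id].iloc[0]
        if row["phenotype"] in ("etomidate_like", "toxic") and np.isfinite(row["ec50_uM"]):
            bell = row.get("ec50_hi_uM", np.nan)
            if np.isfinite(bell):
                return DoseLaw(ec50_uM=row["ec50_uM"], ec50_hi_uM=float(bell))
            return DoseLaw(ec50_uM=row["ec50_uM"])
        return None


def _random_fingerprints(rng, n: int, n_bits: int, density: float) -> np.ndarray:
    return rng.random((n, n_bits)) < density


def generate_compound_library(
    n_clusters: int = 14,
    cluster_size: int = 9,
    n_bits: int = 512,
    target_panel: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    *,
    flip_rate: float = 0.05,
    bit_density: float = 0.1,
    n_singletons: int = 0,
) -> SyntheticLibrary:
    """Library with planted structural clusters and planted target annotations.

    Each cluster's members mutate a seed fingerprint at ``flip_rate`` per bit,
    so within-cluster Tanimoto exceeds between-cluster Tanimoto in
    expectation.  ``target_panel`` maps target_id -> {"clusters": [...],
    "rate_in": p, "rate_out": q}: members of the listed clusters are annotated
    with probability p, others with probability q.
    """
    if n_bits < 64:
        raise InvalidInputError("n_bits must be >= 64")
    if not 0.0 <= flip_rate <= 1.0:
        raise InvalidInputError("flip_rate must be in [0, 1]")
    rng = np.random.default_rng(_seed_seq(seed, 10))
    if target_panel is None:
        target_panel = {
            "GABAA": {"clusters": list(range(min(3, n_clusters))), "rate_in": 0.8, "rate_out": 0.05},
            "HTR6": {"clusters": [min(3, n_clusters - 1)], "rate_in": 0.7, "rate_out": 0.05},
        }
    compounds: list[CompoundRecord] = []
    rows = []
    idx = 0
    for c in range(n_clusters):
        seed_fp = rng.random(n_bits) < bit_density
        for _ in range(cluster_size):
            flips = rng.random(n_bits) < flip_rate
            fp = np.logical_xor(seed_fp, flips)
            targets = tuple(
                t for t, spec in target_panel.items()
                if rng.random() < (spec["rate_in"] if c in spec["clusters"] else spec["rate_out"])
            )
            cid = f"L{idx:05d}"
            compounds.append(CompoundRecord(cid, fp, targets=targets))
            rows.append({"compound_id": cid, "phenotype": "inactive", "cluster": c,
                         "ec50_uM": np.nan, "ec50_hi_uM": np.nan})
            idx += 1
    for fp in _random_fingerprints(rng, n_singletons, n_bits, bit_density):
        cid = f"L{idx:05d}"
        targets = tuple(
            t for t, spec in target_panel.items() if rng.random() < spec["rate_out"]
        )
        compounds.append(CompoundRecord(cid, fp, targets=targets))
        rows.append({"compound_id": cid, "phenotype": "inactive", "cluster": -1,
                     "ec50_uM": np.nan, "ec50_hi_uM": np.nan})
        idx += 1
    return SyntheticLibrary(compounds, pd.DataFrame(rows))


def generate_screen(
    n_compounds: int,
    hit_fraction: float,
    toxic_fraction: float,
    seed,
    *,
    n_replicates: int = 1,
    control_fraction: float = 0.25,
    n_bits: int = 512,
    battery: StimulusTrain | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> tuple[list[BehavioralProfile], SyntheticLibrary]:
    """A single-concentration screen with planted hits and toxics.

    Exact counts round(n * fraction) of compounds are assigned the
    etomidate-like and toxic classes; all compounds are profiled at the
    screening concentration (10 uM) alongside DMSO control wells.  Planted
    hits are grouped into structural fingerprint clusters of about 9; other
    compounds get random fingerprints.
    """
    if not (0 <= hit_fraction <= 1 and 0 <= toxic_fraction <= 1 and hit_fraction + toxic_fraction <= 1):
        raise InvalidInputError("fractions must lie in [0,1] and sum to <= 1")
    n_hits = round(n_compounds * hit_fraction)
    n_toxic = round(n_compounds * toxic_fraction)
    rng = np.random.default_rng(_seed_seq(seed, 20))
    classes = (["etomidate_like"] * n_hits + ["toxic"] * n_toxic
               + ["inactive"] * (n_compounds - n_hits - n_toxic))
    rng.shuffle(classes)

    # fingerprints: hits share planted clusters, everything else is random
    hit_positions = [i for i, c in enumerate(classes) if c == "etomidate_like"]
    cluster_of: dict[int, int] = {}
    cluster_size = 9
    for j, pos in enumerate(hit_positions):
        cluster_of[pos] = j // cluster_size
    n_hit_clusters = (len(hit_positions) + cluster_size - 1) // cluster_size
    cluster_seeds = _random_fingerprints(rng, max(n_hit_clusters, 1), n_bits, 0.1)

    battery = battery or generate_battery()
    compounds: list[CompoundRecord] = []
    rows = []
    profiles: list[BehavioralProfile] = []
    for i, cls in enumerate(classes):
        cid = f"C{i:05d}"
        if i in cluster_of:
            base_fp = cluster_seeds[cluster_of[i]]
            fp = np.logical_xor(base_fp, rng.random(n_bits) < 0.05)
        else:
            fp = rng.random(n_bits) < 0.1
        ec50 = float(np.exp(rng.normal(0.0, 0.3))) if cls in ("etomidate_like", "toxic") else np.nan
        compounds.append(CompoundRecord(cid, fp))
        rows.append({"compound_id": cid, "phenotype": cls, "cluster": cluster_of.get(i, -1),
                     "ec50_uM": ec50, "ec50_hi_uM": np.nan})
        law = DoseLaw(ec50_uM=ec50) if np.isfinite(ec50) else None
        for r in range(n_replicates):
            profiles.append(
                generate_well_profile(
                    CLASS_DEFAULTS[cls],
                    law,
                    config.screening_concentration_uM,
                    battery,
                    _seed_seq(seed, 21, i, r),
                    config=config,
                    well_id=f"{cid}_r{r}",
                    treatment=cid,
                )
            )
    n_controls = round(n_compounds * control_fraction)
    for i in range(n_controls):
        profiles.append(
            generate_well_profile(
                CLASS_DEFAULTS["dmso"], None, 0.0, battery, _seed_seq(seed, 22, i),
                config=config, well_id=f"DMSO{i:04d}", treatment="DMSO",
            )
        )
    return profiles, SyntheticLibrary(compounds, pd.DataFrame(rows))


def generate_dose_series(
    class_params: PhenotypeClassParams,
    dose_law: DoseLaw | None,
    concentrations: Sequence[float] | None = None,
    replicates: int = 12,
    seed=0,
    *,
    battery: StimulusTrain | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
    noise_free: bool = False,
    compound_id: str = "CMPD",
) -> list[BehavioralProfile]:
    """Replicate wells across a concentration ladder following a dose law.

    Default ladder: 7 half-log steps from 0.1 to 100 uM.
    """
    if concentrations is None:
        concentrations = default_dose_ladder()
    concentrations = [float(c) for c in concentrations]
    if any(c <= 0 for c in concentrations):
        raise InvalidInputError("concentrations must be > 0")
    battery = battery or generate_battery()
    profiles = []
    for ci, conc in enumerate(concentrations):
        for r in range(replicates):
            profiles.append(
                generate_well_profile(
                    class_params, dose_law, conc, battery, _seed_seq(seed, 30, ci, r),
                    config=config, noise_free=noise_free,
                    well_id=f"{compound_id}_c{ci}_r{r}", treatment=compound_id,
                )
            )
    return profiles


def default_dose_ladder() -> list[float]:
    """Seven half-log concentrations spanning 0.1-100 uM."""
    return list(np.round(10.0 ** np.linspace(-1, 2, 7), 4))


# --------------------------------------------------------------------------
# frame stacks (for exercising compute_motion_index)
# --------------------------------------------------------------------------

def generate_frame_stack(
    n_frames: int = 50,
    height: int = 32,
    width: int = 32,
    n_blobs: int = 8,
    seed=0,
    *,
    frame_rate: float = 25.0,
    blob_sigma: float = 1.5,
    step_px: float = 1.5,
) -> FrameStack:
    """Blob-based synthetic video: Gaussian spots doing a random walk.

    Deliberately cartoonish — it exists to exercise per-pixel motion-index
    extraction, not to look like real larvae.
    """
    if n_frames < 2:
        raise InvalidInputError("need at least 2 frames")
    rng = np.random.default_rng(_seed_seq(seed, 40))
    pos = rng.uniform([0, 0], [height - 1, width - 1], size=(n_blobs, 2))
    yy, xx = np.mgrid[0:height, 0:width]
    frames = np.zeros((n_frames, height, width))
    for t in range(n_frames):
        pos = np.clip(pos + rng.normal(0, step_px, pos.shape), 0, [height - 1, width - 1])
        for y, x in pos:
            frames[t] += np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * blob_sigma**2))
    frames *= 255.0 / frames.max()
    return FrameStack(frames=frames, frame_rate=frame_rate)
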