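"""Readers/writers for the pipeline's delimited-text and JSON interchange.

Profiles travel as long-format CSV (well_id, plate_id, treatment,
concentration_uM, t_s, mi); stimulus trains as YAML/JSON config; references
as JSON; fingerprint libraries as (compound_id, bitstring) TSV; target
annotations as (compound_id, target_id) TSV; Ki panels as compound x
receptor CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .chem import BindingPanel, CompoundRecord
from .errors import InvalidInputError
from .phenoscore import AnnealConfig, PhenoscoreResult, ReferenceProfile
from .profile_core import BehavioralProfile, StimulusEvent, StimulusTrain

PROFILE_COLUMNS = ["well_id", "plate_id", "treatment", "concentration_uM", "t_s", "mi"]


def profiles_to_frame(profiles: Sequence[BehavioralProfile]) -> pd.DataFrame:
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "well_id": p.well_id,
            "plate_id": p.plate_id,
            "treatment": p.treatment,
            "concentration_uM": p.concentration_uM,
            "t_s": p.times_s,
            "mi": p.mi,
        }))
    return pd.concat(frames, ignore_index=True)[PROFILE_COLUMNS]


def write_profiles(profiles: Sequence[BehavioralProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path, stimulus_train: StimulusTrain) -> list[BehavioralProfile]:
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"profile table missing columns: {sorted(missing)}")
    out = []
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("t_s")
        dt = np.diff(grp["t_s"].to_numpy())
        rate = 1.0 / float(np.median(dt)) if dt.size else 25.0
        out.append(BehavioralProfile(
            mi=grp["mi"].to_numpy(dtype=float),
            stimulus_train=stimulus_train,
            sample_rate_hz=rate,
            well_id=str(well_id),
            plate_id=str(grp["plate_id"].iloc[0]),
            treatment=str(grp["treatment"].iloc[0]),
            concentration_uM=float(grp["concentration_uM"].iloc[0]),
        ))
    return out


def write_stimulus_train(train: StimulusTrain, path) -> None:
    doc = {
        "total_duration_s": train.total_duration_s,
        "assay_starts": list(train.assay_starts),
        "events": [
            {"kind": e.kind, "onset_s": e.onset_s, "duration_s": e.duration_s,
             "amplitude": e.amplitude}
            for e in train.events
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_stimulus_train(path) -> StimulusTrain:
    doc = yaml.safe_load(Path(path).read_text())
    events = tuple(
        StimulusEvent(e["kind"], e["onset_s"], e["duration_s"], e.get("amplitude", 1.0))
        for e in doc["events"]
    )
    return StimulusTrain(events, doc["total_duration_s"],
                         tuple(doc.get("assay_starts", (0.0,))))


def write_reference(reference: ReferenceProfile, path) -> None:
    cfg = reference.anneal_config
    doc = {
        "profile": [float(v) for v in reference.profile],
        "member_ids": list(reference.member_ids),
        "objective_value": reference.objective_value,
        "anneal_config": None if cfg is None else {
            "subset_size": cfg.subset_size,
            "n_iterations": cfg.n_iterations,
            "initial_temperature": cfg.initial_temperature,
            "cooling_rate": cfg.cooling_rate,
            "lambda_dmso": cfg.lambda_dmso,
            "seed": cfg.seed,
        },
    }
    Path(path).write_text(json.dumps(doc))


def read_reference(path) -> ReferenceProfile:
    doc = json.loads(Path(path).read_text())
    cfg = doc.get("anneal_config")
    return ReferenceProfile(
        profile=np.asarray(doc["profile"], dtype=float),
        member_ids=tuple(doc["member_ids"]),
        objective_value=float(doc["objective_value"]),
        anneal_config=None if cfg is None else AnnealConfig(**cfg),
    )


def write_scores(scores: Sequence[PhenoscoreResult], path) -> None:
    pd.DataFrame(
        [{"well_id": s.well_id, "phenoscore": s.phenoscore, "degenerate": s.degenerate}
         for s in scores]
    ).to_csv(path, index=False)


def read_scores(path) -> list[PhenoscoreResult]:
    df = pd.read_csv(path)
    return [
        PhenoscoreResult(str(r.well_id), float(r.phenoscore), bool(r.degenerate))
        for r in df.itertuples()
    ]


def write_fingerprints(compounds: Sequence[CompoundRecord], path) -> None:
    rows = [
        {"compound_id": c.compound_id,
         "bitstring": "".join("1" if b else "0" for b in c.fingerprint)}
        for c in compounds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fingerprints(path) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CompoundRecord(r.compound_id, np.frombuffer(r.bitstring.encode(), dtype=np.uint8) == ord("1"))
        for r in df.itertuples()
    ]


def write_annotations(compounds: Sequence[CompoundRecord], path) -> None:
    rows = [
        {"compound_id": c.compound_id, "target_id": t}
        for c in compounds for t in c.targets
    ]
    pd.DataFrame(rows, columns=["compound_id", "target_id"]).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_ki_panel(path, unit: str = "uM") -> BindingPanel:
    return BindingPanel(pd.read_csv(path, index_col=0), unit=unit)
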