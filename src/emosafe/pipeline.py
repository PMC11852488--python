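"""End-to-end orchestration: simulate -> preprocess -> features -> classify
-> behavioral statistics, from a single validated configuration.

Every source of randomness derives from ``PipelineConfig.seed``; running the
same configuration twice produces byte-identical JSON reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import behavior_stats as bs
from .classify import KnnConfig, run_band_comparison
from .features import SampEnParams
from .io import write_report_json, write_trials_csv
from .preprocess import FilterSpec
from .recording import BAND_NAMES, BANDS, STATES
from .synth_behavior import (
    DVS,
    BehaviorEffectSpec,
    generate_trials,
    preset_reported_means,
)
from .synth_eeg import DEFAULT_PROFILES, generate_recording

log = logging.getLogger("emosafe")


@dataclass
class PipelineConfig:
    """All stage parameters in one document.

    Defaults follow the study conventions where stated (fs 128 Hz, 1 s
    windows, 0.5-50 Hz band-pass, the five canonical bands, T7/T8
    channels, 216 s per condition) and the package's documented design
    choices otherwise (SampEn m=2 r=0.2*SD, KNN k=5, stratified 5-fold CV,
    50 Hz notch).
    """

    seed: int = 0
    # synthetic EEG
    states: tuple[str, ...] = STATES
    duration: float = 216.0
    fs: float = 128.0
    # preprocessing
    f_lo: float = 0.5
    f_hi: float = 50.0
    notch_freq: float = 50.0
    window_length: float = 1.0
    amplitude_limit: float = 100.0
    gradient_limit: float = 200.0
    # features
    channels: tuple[str, ...] = ("T7", "T8")
    bands: tuple[str, ...] = BAND_NAMES
    sampen_m: int = 2
    sampen_r: float = 0.2
    # classification
    k: int = 5
    folds: int = 5
    split: str = "epoch"
    # behavioral arm
    n_participants: int = 22
    behavior_preset: str = "reported"  # or "null"

    def validate(self) -> None:
        unknown = [b for b in self.bands if b not in BANDS]
        if unknown:
            raise ValueError(f"unknown band name(s) {unknown}; known: {BAND_NAMES}")
        unknown_states = [s for s in self.states if s not in DEFAULT_PROFILES]
        if unknown_states:
            raise ValueError(f"no shipped profile for state(s) {unknown_states}")
        if self.split not in ("epoch", "subject"):
            raise ValueError(f"unknown split mode {self.split!r}")
        if self.behavior_preset not in ("reported", "null"):
            raise ValueError(f"unknown behavior preset {self.behavior_preset!r}")
        FilterSpec(f_lo=self.f_lo, f_hi=self.f_hi, notch_freq=self.notch_freq).validate(
            self.fs
        )


def behavior_spec(config: PipelineConfig) -> BehaviorEffectSpec:
    if config.behavior_preset == "reported":
        return preset_reported_means(config.n_participants)
    return BehaviorEffectSpec.null(config.n_participants)


def run_behavior_stats(trials, alpha: float = 0.05) -> dict:
    """One-way + two-way ANOVA per DV, simple effects where the interaction
    is significant, and an OLS of participant-mean DVs on personal factors."""
    out: dict = {}
    for dv in DVS:
        y = trials[dv].to_numpy()
        emotion = trials["emotion"].to_numpy()
        psycap = trials["psycap_group"].to_numpy()
        one = bs.one_way_anova(y, emotion, posthoc=True)
        two = bs.two_way_anova(y, emotion, psycap, unbalanced="type2")
        entry = {
            "one_way": one.to_frame(),
            "two_way": two.to_frame(),
        }
        if two.effect("emotion:psycap").p < alpha:
            simples = bs.simple_effects(y, emotion, psycap, focal_name="emotion")
            entry["simple_effects"] = {
                level: res.to_frame() for level, res in simples.items()
            }
        out[dv] = entry

    per_participant = trials.groupby("participant").agg(
        {dv: "mean" for dv in DVS}
        | {c: "first" for c in ("sleep", "smoke", "alcohol", "trainings", "lectures")}
    )
    predictors = per_participant[
        ["sleep", "smoke", "alcohol", "trainings", "lectures"]
    ]
    out["regression"] = {}
    for dv in DVS:
        fit = bs.multiple_regression(per_participant[dv].to_numpy(), predictors)
        out["regression"][dv] = {
            "r_squared": fit.r_squared,
            "coefficients": fit.table.reset_index(names="predictor"),
        }
    return out


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full configured pipeline and return the report bundle.

    If ``out_dir`` is given, writes ``classification_report.json``,
    ``behavior_report.json``, ``band_accuracy.csv`` and ``trials.csv``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    # independent per-stage seeds, all derived from the config seed
    eeg_seeds = {state: int(rng.integers(2**31)) for state in config.states}
    cv_seed = int(rng.integers(2**31))
    behavior_seed = int(rng.integers(2**31))

    log.info("simulating %d states x %.0f s EEG", len(config.states), config.duration)
    recordings = [
        generate_recording(
            DEFAULT_PROFILES[state], config.duration, config.fs, eeg_seeds[state]
        )
        for state in config.states
    ]

    log.info("running per-band classification (%s split, k=%d)", config.split, config.k)
    comparison = run_band_comparison(
        recordings,
        bands=[BANDS[b] for b in config.bands],
        config=KnnConfig(k=config.k),
        filter_spec=FilterSpec(
            f_lo=config.f_lo, f_hi=config.f_hi, notch_freq=config.notch_freq
        ),
        sampen=SampEnParams(m=config.sampen_m, r=config.sampen_r),
        channels=config.channels,
        window_length=config.window_length,
        folds=config.folds,
        seed=cv_seed,
        split=config.split,
    )

    log.info("simulating behavioral trials (%s preset)", config.behavior_preset)
    trials = generate_trials(behavior_spec(config), seed=behavior_seed)
    behavior = run_behavior_stats(trials)

    bundle = {
        "config": asdict(config),
        "classification": {
            "chosen_k": comparison.chosen_k,
            "band_table": comparison.table,
            "reports": {b: r.to_dict() for b, r in comparison.reports.items()},
        },
        "behavior": behavior,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report_json(
            {"config": bundle["config"], **bundle["classification"]},
            out_dir / "classification_report.json",
        )
        write_report_json(
            {"config": bundle["config"], **behavior},
            out_dir / "behavior_report.json",
        )
        comparison.table.to_csv(out_dir / "band_accuracy.csv", index=False)
        write_trials_csv(trials, out_dir / "trials.csv")
    return bundle
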