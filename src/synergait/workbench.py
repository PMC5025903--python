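"""End-to-end pipeline stages with configuration and run manifests.

Three stages tie the library together:

* :func:`run_template_build` — per-subject NMF extraction, unit
  normalization, matching, across-subject averaging and mean - 2 SD
  normative thresholds;
* :func:`run_patient_assessment` — both NNR reconstructions, the four
  impairment metrics and the threshold classification;
* :func:`run_strategy_and_simulate` — impaired-synergy stimulation profiles,
  gating, channel grouping and the phase-warped command log.

Every stage can write a JSON run manifest (command, config snapshot, input
digests, seed, version) from which the outputs are exactly reproducible:
all stochastic steps are re-seeded from the manifest seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .envelope import EnvelopeStrideSet
from .errors import ConfigError, InvalidParameterError
from .gait import GaitEventStream, simulate_session
from .impairment import (
    ImpairmentReport,
    assess_patient,
    healthy_metric_samples,
    normative_thresholds,
)
from .stimulation import (
    DEFAULT_FREQUENCY_HZ,
    DEFAULT_PHASE_BOUNDS,
    DEFAULT_PW_MAX_US,
    build_strategy,
)
from .synergy import GaitSynergyModel, SynergySet, average_group
from .synthetic import make_canonical_template

__all__ = [
    "RunManifest",
    "validate_config",
    "run_template_build",
    "run_patient_assessment",
    "run_strategy_and_simulate",
    "TEMPLATE_CONFIG_KEYS",
    "STRATEGY_CONFIG_KEYS",
]

TEMPLATE_CONFIG_KEYS = {
    "n_synergies": (int, type(None)),
    "n_restarts": (int,),
    "max_iter": (int,),
    "tol": (float, int),
}
ASSESS_CONFIG_KEYS = {"max_iter": (int,), "tol": (float, int)}
STRATEGY_CONFIG_KEYS = {
    "pw_max_us": (int,),
    "frequency_hz": (float, int),
    "cosine_threshold": (float,),
    "phase_bounds": (list, tuple),
    "amplitudes_ma": (dict,),
}


def validate_config(config: dict | None, allowed: dict[str, tuple]) -> dict:
    """Reject unknown keys and wrong-typed values; silent config drift is the
    main reproducibility hazard in multi-stage pipelines."""
    config = dict(config or {})
    for key, value in config.items():
        if key not in allowed:
            raise ConfigError(f"unknown config key '{key}'; allowed: {sorted(allowed)}")
        if not isinstance(value, allowed[key]):
            raise ConfigError(
                f"config key '{key}' must be of type {allowed[key]}, got {type(value).__name__}"
            )
    return config


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = __version__
    timestamp: str = ""
    python: str = platform.python_version()

    def write(self, path) -> None:
        doc = {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "version": self.version,
            "timestamp": self.timestamp or datetime.now(timezone.utc).isoformat(),
            "python": self.python,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def run_template_build(
    subjects: list[EnvelopeStrideSet],
    config: dict | None = None,
    seed: int = 0,
    reference: SynergySet | None = None,
) -> tuple[SynergySet, dict[str, float], list[SynergySet]]:
    """Build the healthy template and normative thresholds from a cohort.

    Each subject's envelopes are factorized (4 synergies unless configured
    otherwise), unit-normalized and matched to the labeling reference (the
    canonical template by default); the matched sets are averaged and each
    subject is then re-assessed against the group mean to pool the four
    metrics into mean - 2 SD thresholds.

    Returns (template, thresholds, per-subject matched synergy sets).
    """
    if len(subjects) < 2:
        raise InvalidParameterError(
            f"cohort of {len(subjects)} subject(s); at least 2 required"
        )
    cfg = validate_config(config, TEMPLATE_CONFIG_KEYS)
    n_synergies = cfg.get("n_synergies", 4)
    n_restarts = cfg.get("n_restarts", 20)
    max_iter = cfg.get("max_iter", 1000)
    tol = cfg.get("tol", 1e-6)
    muscles = list(subjects[0].muscle_names)
    for i, s in enumerate(subjects):
        if list(s.muscle_names) != muscles:
            raise InvalidParameterError(
                f"template build, subject {i}: muscle set {s.muscle_names} != {muscles}"
            )
    if reference is None:
        reference = make_canonical_template(muscles)
    rng = np.random.default_rng(seed)
    subject_sets: list[SynergySet] = []
    for i, s in enumerate(subjects):
        try:
            res = GaitSynergyModel(s).fit(
                n_synergies=n_synergies,
                seed=int(rng.integers(2**31)),
                n_restarts=n_restarts,
                max_iter=max_iter,
                tol=tol,
            )
        except Exception as exc:  # surface the failing stage and subject
            raise type(exc)(f"template build, extraction, subject {i}: {exc}") from exc
        subject_sets.append(res.match_to(reference).synergies)
    template = average_group(subject_sets, reference)
    samples = healthy_metric_samples(
        subjects, template, seed=int(rng.integers(2**31)), max_iter=max_iter
    )
    thresholds = normative_thresholds(samples)
    return template, thresholds, subject_sets


def run_patient_assessment(
    patient: EnvelopeStrideSet,
    template: SynergySet,
    thresholds: dict[str, float],
    config: dict | None = None,
    seed: int = 0,
) -> ImpairmentReport:
    """Assess one patient against the healthy template and thresholds."""
    cfg = validate_config(config, ASSESS_CONFIG_KEYS)
    if list(patient.muscle_names) != list(template.muscle_names):
        raise InvalidParameterError(
            f"patient muscles {patient.muscle_names} != template {template.muscle_names}"
        )
    return assess_patient(
        patient,
        template,
        thresholds,
        seed=seed,
        max_iter=cfg.get("max_iter", 1000),
        tol=cfg.get("tol", 1e-8),
    )


def run_strategy_and_simulate(
    report: ImpairmentReport,
    template: SynergySet,
    config: dict | None = None,
    events: GaitEventStream | None = None,
):
    """Build the stimulation strategy from the impaired synergies and, when
    an event stream is supplied, simulate the phase-warped command log.

    Returns (strategy, commands) with ``commands=None`` when no events are given.
    """
    cfg = validate_config(config, STRATEGY_CONFIG_KEYS)
    strategy = build_strategy(
        template,
        report.impaired_labels,
        amplitudes_ma=cfg.get("amplitudes_ma"),
        pw_max_us=cfg.get("pw_max_us", DEFAULT_PW_MAX_US),
        frequency_hz=cfg.get("frequency_hz", DEFAULT_FREQUENCY_HZ),
        template_phase_bounds=tuple(cfg.get("phase_bounds", DEFAULT_PHASE_BOUNDS)),
        cosine_threshold=cfg.get("cosine_threshold", 0.99),
    )
    commands = simulate_session(strategy, events) if events is not None else None
    return strategy, commands
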