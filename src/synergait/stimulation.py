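"""Personalized multi-channel FES stimulation strategy.

The biomimetic drive for each muscle is rebuilt from the healthy template
restricted to the patient's impaired synergies, EMG = W_healthy[:, impaired]
* H_healthy[impaired, :]. Profiles are gated to zero below the fatigue
threshold (baseline + 20% of peak-to-peak amplitude), rescaled per muscle to
a normalized [0, 1] intensity, and muscles with near-identical gated profiles
are grouped onto a single stimulation channel. Intensity maps linearly to
pulse width (0 to 400 us by default) at a common 20 Hz rate; per-channel
current amplitude comes from clinical calibration and is carried as
configuration, never computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .envelope import N_CYCLE_POINTS
from .errors import InvalidParameterError
from .synergy import SynergySet, cosine_similarity, normalize_unit

DEFAULT_PW_MAX_US = 400
DEFAULT_FREQUENCY_HZ = 20.0
# template gait-phase fractions (paretic DS, np initial swing, np terminal
# swing, np DS, paretic initial swing, paretic terminal swing)
DEFAULT_PHASE_BOUNDS = (0.12, 0.19, 0.19, 0.12, 0.19, 0.19)

__all__ = [
    "StimulationChannel",
    "StimulationStrategy",
    "build_profiles",
    "apply_activation_threshold",
    "group_channels",
    "to_pulse_width",
    "build_strategy",
    "DEFAULT_PW_MAX_US",
    "DEFAULT_FREQUENCY_HZ",
    "DEFAULT_PHASE_BOUNDS",
]


@dataclass
class StimulationChannel:
    """One stimulation channel driving a muscle group."""

    name: str
    muscles: list[str]
    profile: np.ndarray  # 100-point normalized intensity in [0, 1]
    amplitude_ma: float = 0.0

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (N_CYCLE_POINTS,):
            raise InvalidParameterError(f"channel profile must have {N_CYCLE_POINTS} points")
        if self.profile.min() < 0 or self.profile.max() > 1 + 1e-9:
            raise InvalidParameterError("channel intensities must lie in [0, 1]")


@dataclass
class StimulationStrategy:
    """Complete per-patient stimulation template."""

    channels: list[StimulationChannel]
    pw_max_us: int = DEFAULT_PW_MAX_US
    frequency_hz: float = DEFAULT_FREQUENCY_HZ
    template_phase_bounds: tuple[float, ...] = DEFAULT_PHASE_BOUNDS
    impaired_labels: list[str] = field(default_factory=list)
    no_stimulation: bool = False
    muscle_scale_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bounds = np.asarray(self.template_phase_bounds, dtype=float)
        if bounds.size != 6 or np.any(bounds <= 0) or abs(bounds.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                "template_phase_bounds must be 6 positive fractions summing to 1"
            )
        seen: set[str] = set()
        for ch in self.channels:
            overlap = seen.intersection(ch.muscles)
            if overlap:
                raise InvalidParameterError(f"muscle(s) {overlap} assigned to multiple channels")
            seen.update(ch.muscles)

    def to_json(self) -> str:
        return json.dumps(
            {
                "channels": [
                    {
                        "name": ch.name,
                        "muscles": ch.muscles,
                        "profile": ch.profile.tolist(),
                        "amplitude_ma": ch.amplitude_ma,
                    }
                    for ch in self.channels
                ],
                "pw_max_us": self.pw_max_us,
                "frequency_hz": self.frequency_hz,
                "template_phase_bounds": list(self.template_phase_bounds),
                "impaired_labels": self.impaired_labels,
                "no_stimulation": self.no_stimulation,
                "muscle_scale_factors": self.muscle_scale_factors,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulationStrategy":
        doc = json.loads(text)
        return cls(
            channels=[
                StimulationChannel(
                    c["name"], list(c["muscles"]), np.array(c["profile"]), c.get("amplitude_ma", 0.0)
                )
                for c in doc["channels"]
            ],
            pw_max_us=doc.get("pw_max_us", DEFAULT_PW_MAX_US),
            frequency_hz=doc.get("frequency_hz", DEFAULT_FREQUENCY_HZ),
            template_phase_bounds=tuple(doc.get("template_phase_bounds", DEFAULT_PHASE_BOUNDS)),
            impaired_labels=list(doc.get("impaired_labels", [])),
            no_stimulation=doc.get("no_stimulation", False),
            muscle_scale_factors=dict(doc.get("muscle_scale_factors", {})),
        )

    def summary(self) -> str:
        lines = [
            "Stimulation strategy "
            f"(pulse width 0-{self.pw_max_us} us, {self.frequency_hz:g} Hz)",
            f"  impaired synergies driving the strategy: "
            + (", ".join(self.impaired_labels) or "none"),
        ]
        if self.no_stimulation:
            lines.append("  no impaired synergies: no stimulation needed")
        for ch in self.channels:
            lines.append(
                f"  channel {ch.name}: muscles {'+'.join(ch.muscles)}, "
                f"peak {to_pulse_width(ch.profile.max(), self.pw_max_us)} us, "
                f"amplitude {ch.amplitude_ma:g} mA"
            )
        return "\n".join(lines)


def build_profiles(
    template: SynergySet,
    impaired: list[str] | set[str],
    recruitment_floor: float = 0.10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-muscle drive profiles from the impaired synergies only.

    Returns ``(profiles, scale_factors, no_stimulation)``: the N x 100 product
    of the impaired columns of W_healthy with the matching rows of H_healthy,
    rescaled per muscle to peak 1 (all-zero muscles keep scale 1 and a zero
    profile). A muscle whose peak drive is below ``recruitment_floor`` times
    the strongest muscle's is treated as not recruited by the impaired
    synergies and receives no stimulation: cohort-averaged templates carry a
    small positive noise floor on every weight, and per-muscle rescaling
    would otherwise amplify it to full intensity. An empty impaired set is an
    explicit no-stimulation result.
    """
    impaired = list(impaired)
    unknown = set(impaired) - set(template.labels)
    if unknown:
        raise InvalidParameterError(f"unknown synergy label(s): {sorted(unknown)}")
    tmpl = normalize_unit(template)
    n = len(tmpl.muscle_names)
    if not impaired:
        return np.zeros((n, N_CYCLE_POINTS)), np.ones(n), True
    cols = [tmpl.labels.index(lab) for lab in tmpl.labels if lab in impaired]
    profiles = tmpl.W[:, cols] @ tmpl.mean_profiles()[cols, :]
    peaks = profiles.max(axis=1)
    profiles[peaks < recruitment_floor * peaks.max()] = 0.0
    scale = profiles.max(axis=1)
    factors = np.where(scale > 0, scale, 1.0)
    return profiles / factors[:, None], factors, False


def apply_activation_threshold(profile: np.ndarray, rel_threshold: float = 0.20) -> np.ndarray:
    """Zero the profile wherever it is strictly below baseline + 20% of the
    peak-to-peak amplitude (fatigue gating); flat profiles go entirely to zero."""
    profile = np.asarray(profile, dtype=float)
    ptp = profile.max() - profile.min()
    if ptp < 1e-9:
        return np.zeros_like(profile)
    thr = profile.min() + rel_threshold * ptp
    out = profile.copy()
    out[out < thr] = 0.0
    return out


def group_channels(
    profiles: np.ndarray,
    muscle_names: list[str],
    cosine_threshold: float = 0.99,
) -> list[StimulationChannel]:
    """Group muscles with very similar gated profiles onto shared channels.

    Greedy single-linkage agglomeration in muscle order: two muscles join the
    same channel when the cosine of their gated profiles is at least
    ``cosine_threshold``. All-zero muscles receive no channel. The merged
    channel profile is the member mean rescaled to peak 1.
    """
    profiles = np.asarray(profiles, dtype=float)
    active = [i for i in range(len(muscle_names)) if profiles[i].max() > 0]
    parent = {i: i for i in active}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_pos, i in enumerate(active):
        for j in active[a_pos + 1 :]:
            if cosine_similarity(profiles[i], profiles[j]) >= cosine_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in active:
        clusters.setdefault(find(i), []).append(i)

    channels = []
    for root in sorted(clusters):
        members = sorted(clusters[root])
        mean = profiles[members].mean(axis=0)
        mean = mean / mean.max()
        names = [muscle_names[i] for i in members]
        channels.append(StimulationChannel("+".join(names), names, mean))
    return channels


def to_pulse_width(intensity, pw_max_us: int = DEFAULT_PW_MAX_US):
    """Linear map from normalized intensity in [0, 1] to integer microseconds."""
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1 + 1e-12):
        raise InvalidParameterError("intensity must lie in [0, 1]")
    out = np.rint(arr * pw_max_us).astype(int)
    return int(out) if np.isscalar(intensity) else out


def build_strategy(
    template: SynergySet,
    impaired: list[str] | set[str],
    amplitudes_ma: dict[str, float] | None = None,
    pw_max_us: int = DEFAULT_PW_MAX_US,
    frequency_hz: float = DEFAULT_FREQUENCY_HZ,
    template_phase_bounds: tuple[float, ...] = DEFAULT_PHASE_BOUNDS,
    cosine_threshold: float = 0.99,
    recruitment_floor: float = 0.10,
) -> StimulationStrategy:
    """Full strategy: impaired-synergy profiles -> gating -> grouping.

    ``amplitudes_ma`` maps muscle name to the clinically calibrated current;
    a channel takes the maximum over its member muscles.
    """
    profiles, factors, empty = build_profiles(template, impaired, recruitment_floor)
    gated = np.vstack([apply_activation_threshold(p) for p in profiles])
    channels = group_channels(gated, template.muscle_names, cosine_threshold)
    if amplitudes_ma:
        for ch in channels:
            ch.amplitude_ma = max(amplitudes_ma.get(m, 0.0) for m in ch.muscles)
    return StimulationStrategy(
        channels=channels,
        pw_max_us=pw_max_us,
        frequency_hz=frequency_hz,
        template_phase_bounds=tuple(template_phase_bounds),
        impaired_labels=list(impaired),
        no_stimulation=empty,
        muscle_scale_factors={m: float(f) for m, f in zip(template.muscle_names, factors)},
    )
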