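"""Ground-truth synthetic gait EMG and gait-event generation.

The generator emulates the statistical structure of healthy gait EMG
envelopes built from four canonical synergies, and stroke-like deviations
from them, so that every pipeline stage is testable without recorded data:

* a canonical 4-synergy template — weight acceptance (WA: gluteus maximus +
  vastus medialis, early stance), push off (PO: plantar-flexors, late
  stance), foot clearance (FC: rectus femoris + tibialis anterior, two
  bursts: early stance and early swing) and leg deceleration (LD: hamstrings,
  late swing wrapping into early stance), with raised-cosine activation
  bursts;
* healthy cohorts: per-subject weight perturbations, systematic timing
  offsets and burst-width scaling, plus per-stride timing jitter, gain
  variation and additive truncated-Gaussian envelope noise;
* stroke-like patients: deficits applied to the template itself — merged
  synergy pairs (summed weights driven by the union of their bursts),
  circular activation shifts (negative = early recruitment) and burst
  widening — over the same stride-level noise model;
* gait-event streams with configurable per-phase mean durations and
  variability.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envelope import EnvelopeStrideSet, N_CYCLE_POINTS
from .errors import InvalidParameterError
from .gait import GaitEvent, GaitEventStream, _PHASE_END_EVENTS
from .synergy import CANONICAL_LABELS, SynergySet, normalize_unit

DEFAULT_MUSCLES = ["GM", "RF", "VM", "HM", "HL", "MG", "SO", "TA"]

# canonical synergy composition: primary muscles carry the synergy, small
# cross-talk weights (<= 0.15) add realism without changing its identity
_WEIGHT_TABLE: dict[str, dict[str, float]] = {
    "WA": {"GM": 0.55, "VM": 0.80, "RF": 0.15},
    "PO": {"MG": 0.75, "SO": 0.65},
    "FC": {"RF": 0.60, "TA": 0.80},
    "LD": {"HM": 0.70, "HL": 0.70, "GM": 0.15},
}
_PRIMARY_MUSCLES: dict[str, tuple[str, ...]] = {
    "WA": ("GM", "VM"),
    "PO": ("MG",),
    "FC": ("RF", "TA"),
    "LD": ("HM", "HL"),
}
# (center, width) in % gait cycle of each raised-cosine activation burst
_BURST_TABLE: dict[str, list[tuple[float, float]]] = {
    "WA": [(14.0, 26.0)],
    "PO": [(47.0, 28.0)],
    "FC": [(4.0, 12.0), (66.0, 24.0)],
    "LD": [(92.0, 24.0)],
}

__all__ = [
    "SynthConfig",
    "DEFAULT_MUSCLES",
    "make_canonical_template",
    "make_healthy_cohort",
    "make_stroke_patient",
    "make_event_stream",
    "DEFAULT_PHASE_DURATIONS_S",
]

# healthy per-phase mean durations (s) for a ~1.1 s gait cycle: double
# supports ~12% of the cycle each, swings split ~19/19
DEFAULT_PHASE_DURATIONS_S = (0.13, 0.21, 0.21, 0.13, 0.21, 0.21)


@dataclass
class SynthConfig:
    """Stride-level generation conditions.

    noise_sd is the additive envelope noise SD as a fraction of the peak
    envelope amplitude; timing_jitter_sd is the per-stride circular shift SD
    in cycle points; stride_gain_sd scales each synergy's per-stride
    recruitment strength.
    """

    n_strides: int = 20
    noise_sd: float = 0.05
    timing_jitter_sd: float = 2.0
    stride_gain_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.timing_jitter_sd < 0 or self.stride_gain_sd < 0:
            raise InvalidParameterError("variability parameters must be nonnegative")
        if self.n_strides < 0:
            raise InvalidParameterError("n_strides must be nonnegative")


def _raised_cosine(center: float, width: float, n: int = N_CYCLE_POINTS) -> np.ndarray:
    """Circular raised-cosine burst, peak 1, support of length ``width``."""
    t = np.arange(n, dtype=float)
    delta = (t - center + n / 2) % n - n / 2
    burst = np.where(np.abs(delta) <= width / 2, 0.5 * (1 + np.cos(2 * np.pi * delta / width)), 0.0)
    return burst


def _circular_sample(h: np.ndarray, positions: np.ndarray) -> np.ndarray:
    n = h.size
    pos = np.mod(positions, n)
    i0 = np.floor(pos).astype(int) % n
    frac = pos - np.floor(pos)
    return h[i0] * (1 - frac) + h[(i0 + 1) % n] * frac


def _shift_profile(h: np.ndarray, shift: float) -> np.ndarray:
    """Circularly shift a profile by ``shift`` points (positive = later)."""
    if float(shift).is_integer():
        return np.roll(h, int(shift))
    return _circular_sample(h, np.arange(h.size, dtype=float) - shift)


def _burst_centers(h: np.ndarray, rel_threshold: float = 0.20) -> np.ndarray:
    """Peak location of each supra-threshold burst (circular domain)."""
    n = h.size
    ptp = h.max() - h.min()
    above = h > h.min() + rel_threshold * ptp
    if above.all():
        return np.array([int(np.argmax(h))], dtype=float)
    start = int(np.argmin(above))  # rotate so scanning starts outside a burst
    centers, run = [], []
    for i in (np.arange(n) + start) % n:
        if above[i]:
            run.append(i)
        elif run:
            centers.append(run[int(np.argmax(h[run]))])
            run = []
    if run:
        centers.append(run[int(np.argmax(h[run]))])
    return np.asarray(centers, dtype=float)


def _scale_width(h: np.ndarray, scale: float) -> np.ndarray:
    """Widen (scale > 1) or narrow each burst about its own center.

    Scaling locally per burst keeps multi-burst profiles in place: a global
    rescale about the profile peak would translate secondary bursts, which is
    a timing shift, not a duration change.
    """
    if scale <= 0:
        raise InvalidParameterError("width scale must be positive")
    if scale == 1.0 or h.max() - h.min() < 1e-9:
        return h.copy()
    n = h.size
    centers = _burst_centers(h)
    t = np.arange(n, dtype=float)
    d = (t[:, None] - centers[None, :] + n / 2) % n - n / 2
    nearest = np.argmin(np.abs(d), axis=1)
    delta = d[np.arange(n), nearest]
    return _circular_sample(h, centers[nearest] + delta / scale)


def make_canonical_template(muscles: list[str] | None = None) -> SynergySet:
    """Canonical healthy 4-synergy gait template.

    Unit-norm weight columns with support on the named muscle groups;
    100-point raised-cosine activation profiles with peak 1 (FC has two
    bursts; LD wraps the cycle boundary).
    """
    if muscles is None:
        muscles = list(DEFAULT_MUSCLES)
    for label, primaries in _PRIMARY_MUSCLES.items():
        missing = [m for m in primaries if m not in muscles]
        if missing:
            raise InvalidParameterError(
                f"synergy {label} requires muscle(s) {missing} absent from {muscles}"
            )
    W = np.zeros((len(muscles), 4))
    H = np.zeros((4, N_CYCLE_POINTS))
    for j, label in enumerate(CANONICAL_LABELS):
        for m, w in _WEIGHT_TABLE[label].items():
            if m in muscles:
                W[muscles.index(m), j] = w
        for center, width in _BURST_TABLE[label]:
            H[j] = np.maximum(H[j], _raised_cosine(center, width))
    # unit-norm weights with peak-1 profiles (no product-preserving rescale:
    # the template is a definition, not a factorization of data)
    W = W / np.linalg.norm(W, axis=0)
    return SynergySet(list(muscles), W, H, list(CANONICAL_LABELS))


def _generate_strides(
    W: np.ndarray,
    H: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """n_strides x muscles x 100 envelopes: per-stride timing jitter, gain
    variation and truncated-Gaussian additive noise."""
    J = H.shape[0]
    clean_peak = (W @ H).max()
    strides = np.empty((config.n_strides, W.shape[0], N_CYCLE_POINTS))
    for k in range(config.n_strides):
        Hk = np.empty_like(H)
        for j in range(J):
            shift = round(rng.normal(0.0, config.timing_jitter_sd)) if config.timing_jitter_sd else 0
            gain = max(0.1, 1.0 + rng.normal(0.0, config.stride_gain_sd)) if config.stride_gain_sd else 1.0
            Hk[j] = gain * _shift_profile(H[j], shift)
        stride = W @ Hk
        if config.noise_sd:
            stride = stride + rng.normal(0.0, config.noise_sd * clean_peak, size=stride.shape)
        strides[k] = np.clip(stride, 0.0, None)
    return strides


def make_healthy_cohort(
    template: SynergySet,
    n_subjects: int = 13,
    between_subject_sd: float = 0.10,
    subject_shift_sd: float = 2.0,
    subject_width_sd: float = 0.10,
    config: SynthConfig | None = None,
    return_truth: bool = False,
):
    """Simulate a healthy cohort around the canonical template.

    Each subject gets perturbed unit-norm weights (truncated-at-zero Gaussian
    noise of SD ``between_subject_sd``), a systematic integer timing offset
    per synergy (SD ``subject_shift_sd`` points) and a burst-width scale
    (lognormal-like, SD ``subject_width_sd``), then ``config.n_strides``
    strides are generated with the stride-level noise model.

    Returns a list of :class:`EnvelopeStrideSet`; with ``return_truth`` also
    the per-subject ground-truth :class:`SynergySet`.
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    tmpl = normalize_unit(template)
    subjects, truths = [], []
    for _ in range(n_subjects):
        Ws = np.clip(tmpl.W + rng.normal(0.0, between_subject_sd, size=tmpl.W.shape), 0.0, None)
        norms = np.linalg.norm(Ws, axis=0)
        norms[norms <= 0] = 1.0
        Ws = Ws / norms
        Hs = np.empty_like(tmpl.H)
        for j in range(tmpl.n_synergies):
            shift = round(rng.normal(0.0, subject_shift_sd)) if subject_shift_sd else 0
            width = float(np.clip(1.0 + rng.normal(0.0, subject_width_sd), 0.7, 1.3))
            Hs[j] = _scale_width(_shift_profile(tmpl.H[j], shift), width)
        sub_cfg = SynthConfig(
            n_strides=config.n_strides,
            noise_sd=config.noise_sd,
            timing_jitter_sd=config.timing_jitter_sd,
            stride_gain_sd=config.stride_gain_sd,
            seed=int(rng.integers(2**31)),
        )
        strides = _generate_strides(Ws, Hs, sub_cfg, np.random.default_rng(sub_cfg.seed))
        subjects.append(EnvelopeStrideSet(list(tmpl.muscle_names), strides))
        truths.append(SynergySet(list(tmpl.muscle_names), Ws, Hs, list(tmpl.labels)))
    return (subjects, truths) if return_truth else subjects


def make_stroke_patient(
    template: SynergySet,
    merge_pairs: list[tuple[str, str]] | None = None,
    lag_shift: dict[str, float] | None = None,
    duration_scale: dict[str, float] | None = None,
    config: SynthConfig | None = None,
    return_truth: bool = False,
):
    """Simulate a stroke-like patient by deforming the template.

    ``merge_pairs`` replaces each pair of synergies by a single one (summed,
    renormalized weights driven by the elementwise maximum of the two
    activation profiles); ``lag_shift`` circularly shifts a synergy's profile
    in cycle points (negative = early recruitment); ``duration_scale`` widens
    (> 1) its bursts. With no deficits configured the patient's generative
    model is the template itself, so the only deviation from healthy is the
    stride-level noise.
    """
    merge_pairs = list(merge_pairs or [])
    lag_shift = dict(lag_shift or {})
    duration_scale = dict(duration_scale or {})
    if config is None:
        config = SynthConfig()
    tmpl = normalize_unit(template)
    seen: set[str] = set()
    for a, b in merge_pairs:
        if {a, b} & seen or a == b:
            raise InvalidParameterError(f"merge pairs must be disjoint, got {merge_pairs}")
        seen.update({a, b})
        for lab in (a, b):
            if lab not in tmpl.labels:
                raise InvalidParameterError(f"unknown synergy label '{lab}'")

    labels = list(tmpl.labels)
    W = tmpl.W.copy()
    H = tmpl.H.copy()
    for lab, shift in lag_shift.items():
        H[labels.index(lab)] = _shift_profile(H[labels.index(lab)], shift)
    for lab, scale in duration_scale.items():
        H[labels.index(lab)] = _scale_width(H[labels.index(lab)], scale)

    keep = list(range(len(labels)))
    for a, b in merge_pairs:
        ia, ib = labels.index(a), labels.index(b)
        w = W[:, ia] + W[:, ib]
        W[:, ia] = w / np.linalg.norm(w)
        H[ia] = np.maximum(H[ia], H[ib])
        labels[ia] = f"{a}+{b}"
        keep.remove(ib)
    W, H = W[:, keep], H[keep]
    labels = [labels[i] for i in keep]

    rng = np.random.default_rng(config.seed)
    strides = _generate_strides(W, H, config, rng)
    patient = EnvelopeStrideSet(list(tmpl.muscle_names), strides)
    truth = SynergySet(list(tmpl.muscle_names), W, H, labels)
    return (patient, truth) if return_truth else patient


def make_event_stream(
    phase_durations_s=DEFAULT_PHASE_DURATIONS_S,
    variability_sd: float = 0.0,
    n_strides: int = 20,
    seed: int = 0,
    start_s: float = 0.0,
) -> GaitEventStream:
    """Gait-event stream consistent with the 6-phase cycle.

    Per stride, each phase duration is drawn from a Gaussian around its mean
    and truncated below at 10% of the mean so durations stay positive.
    ``n_strides = 0`` yields an empty stream.
    """
    means = np.asarray(phase_durations_s, dtype=float)
    if means.size != 6 or np.any(means <= 0):
        raise InvalidParameterError("need 6 positive mean phase durations")
    if n_strides == 0:
        return GaitEventStream([])
    rng = np.random.default_rng(seed)
    events = [GaitEvent(start_s, "IC", "paretic")]
    t = start_s
    for _ in range(n_strides):
        for p, (side, etype) in enumerate(_PHASE_END_EVENTS):
            d = means[p]
            if variability_sd:
                d = max(0.1 * means[p], rng.normal(means[p], variability_sd))
            t += d
            events.append(GaitEvent(t, etype, side))
    return GaitEventStream(events)
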