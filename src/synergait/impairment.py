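"""Patient impairment assessment against a healthy synergy template.

The patient's gait EMG envelopes M (muscles x 100*n_strides) are projected
onto healthy synergy space twice with fixed-component non-negative
reconstruction (NNR):

* fixing the healthy weights W and freeing H gives the patient's activation
  profiles (timing information);
* fixing the healthy mean profiles H (tiled across strides) and freeing W
  gives the patient's weights (spatial composition).

Four per-synergy metrics compare reconstruction and template, each in [0, 1]
with 1 = healthy-like:

* ``similarity`` — cosine between patient and healthy weights;
* ``correlation`` — maximum centered circular cross-correlation between
  patient and healthy activation profiles;
* ``t_lag`` — 1 - |lag|/100, where lag (% gait cycle, in [-50, 49]) is where
  the maximal correlation occurs; positive lag = patient delayed;
* ``activation`` — 1 - |d_p - d_h|/100 comparing supra-threshold activation
  durations (threshold: profile minimum + 20% of peak-to-peak amplitude).

Normative thresholds are the pooled healthy mean - 2 SD per metric; a synergy
is impaired when at least one metric falls strictly below its threshold
(equality passes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envelope import EnvelopeStrideSet, N_CYCLE_POINTS
from .errors import InvalidParameterError
from .factorization import FactorizationResult, compute_vaf, nnr_fixed_h, nnr_fixed_w
from .synergy import SynergySet, circular_xcorr_max, cosine_similarity, normalize_unit

METRIC_NAMES = ("similarity", "correlation", "t_lag", "activation")

__all__ = [
    "METRIC_NAMES",
    "NnrResult",
    "TemplateReconstruction",
    "ReconstructionResults",
    "ImpairmentReport",
    "similarity",
    "max_circular_xcorr",
    "t_lag_metric",
    "activation_duration",
    "activation_metric",
    "normative_thresholds",
    "classify_impairment",
    "assess_patient",
    "healthy_metric_samples",
]

similarity = cosine_similarity
max_circular_xcorr = circular_xcorr_max


@dataclass
class NnrResult:
    """One fixed-component reconstruction."""

    fixed: str  # "W" or "H"
    W: np.ndarray
    H: np.ndarray
    vaf_total: float
    vaf_per_muscle: np.ndarray
    per_stride_profiles: np.ndarray | None = None  # J x n_strides x 100
    mean_profile: np.ndarray | None = None  # J x 100
    error_history: np.ndarray | None = None


def _wrap_nnr(fixed: str, res: FactorizationResult, M: np.ndarray) -> NnrResult:
    vaf_total, vaf_pm = compute_vaf(M, res.W, res.H)
    out = NnrResult(fixed, res.W, res.H, vaf_total, vaf_pm, error_history=res.error_history)
    if fixed == "W":
        J, T = res.H.shape
        if T % N_CYCLE_POINTS == 0:
            out.per_stride_profiles = res.H.reshape(J, T // N_CYCLE_POINTS, N_CYCLE_POINTS)
            out.mean_profile = out.per_stride_profiles.mean(axis=1)
    return out


class TemplateReconstruction:
    """Project patient envelopes onto a healthy synergy template.

    Parameters
    ----------
    data : EnvelopeStrideSet or ndarray
        Patient stride envelopes (concatenated internally to
        muscles x 100*n_strides).
    template : SynergySet
        Healthy template; weight columns are unit-normalized before use and
        ``template.mean_profiles()`` supplies the healthy activation profiles.
    """

    def __init__(self, data, template: SynergySet):
        if isinstance(data, EnvelopeStrideSet):
            if list(data.muscle_names) != list(template.muscle_names):
                raise InvalidParameterError(
                    f"muscle sets differ: patient {data.muscle_names} "
                    f"vs template {template.muscle_names}"
                )
            self.endog = data.concatenated()
        else:
            self.endog = np.asarray(data, dtype=float)
        self.template = normalize_unit(template)
        if self.endog.shape[0] != self.template.W.shape[0]:
            raise InvalidParameterError("muscle count mismatch between data and template")
        if self.endog.shape[1] % N_CYCLE_POINTS:
            raise InvalidParameterError(
                f"data length must be a multiple of {N_CYCLE_POINTS} points"
            )

    @property
    def n_strides(self) -> int:
        return self.endog.shape[1] // N_CYCLE_POINTS

    def fit(self, seed: int = 0, max_iter: int = 1000, tol: float = 1e-8) -> "ReconstructionResults":
        rng = np.random.default_rng(seed)
        h_healthy = self.template.mean_profiles()
        res_w = nnr_fixed_w(self.endog, self.template.W, seed=rng, max_iter=max_iter, tol=tol)
        h_tiled = np.tile(h_healthy, (1, self.n_strides))
        res_h = nnr_fixed_h(self.endog, h_tiled, seed=rng, max_iter=max_iter, tol=tol)
        return ReconstructionResults(
            self,
            fixed_w=_wrap_nnr("W", res_w, self.endog),
            fixed_h=_wrap_nnr("H", res_h, self.endog),
        )


class ReconstructionResults:
    """Both NNR fits of one patient.

    ``fixed_w`` frees the activation profiles (timing), ``fixed_h`` frees the
    weights (spatial composition).
    """

    def __init__(self, model: TemplateReconstruction, fixed_w: NnrResult, fixed_h: NnrResult):
        self.model = model
        self.fixed_w = fixed_w
        self.fixed_h = fixed_h

    @property
    def patient_weights(self) -> np.ndarray:
        """Muscles x J weights from the fixed-H reconstruction."""
        return self.fixed_h.W

    @property
    def patient_mean_profiles(self) -> np.ndarray:
        """J x 100 mean activation profiles from the fixed-W reconstruction."""
        return self.fixed_w.mean_profile  # type: ignore[return-value]

    def metrics(self) -> dict[str, dict[str, float]]:
        """Four impairment metrics for each synergy of the template."""
        tmpl = self.model.template
        h_healthy = tmpl.mean_profiles()
        out: dict[str, dict[str, float]] = {}
        for j, label in enumerate(tmpl.labels):
            sim = similarity(self.patient_weights[:, j], tmpl.W[:, j])
            # positive lag = patient delayed relative to healthy
            r, lag = max_circular_xcorr(h_healthy[j], self.patient_mean_profiles[j])
            d_h = activation_duration(h_healthy[j])
            d_p = activation_duration(self.patient_mean_profiles[j])
            out[label] = {
                "similarity": sim,
                "correlation": r,
                "lag": float(lag),
                "t_lag": t_lag_metric(lag),
                "activation": activation_metric(d_p, d_h),
                "duration_patient": d_p,
                "duration_healthy": d_h,
            }
        return out

    def summary(self) -> str:
        lines = [
            "Template reconstruction (NNR, multiplicative updates)",
            f"  strides: {self.model.n_strides}",
            f"  VAF (fixed healthy W, free H): {self.fixed_w.vaf_total:.3f}",
            f"  VAF (fixed healthy H, free W): {self.fixed_h.vaf_total:.3f}",
        ]
        for label, m in self.metrics().items():
            lines.append(
                f"  {label}: similarity={m['similarity']:.2f} "
                f"correlation={m['correlation']:.2f} t_lag={m['t_lag']:.2f} "
                f"activation={m['activation']:.2f} (lag {m['lag']:+.0f}%)"
            )
        return "\n".join(lines)


def t_lag_metric(lag: float) -> float:
    """Timing score 1 - |lag|/100 for a lag in % gait cycle, |lag| <= 50."""
    if abs(lag) > 50:
        raise InvalidParameterError(f"lag {lag} outside [-50, 50] % gait cycle")
    return 1.0 - abs(lag) / 100.0


def activation_duration(h: np.ndarray, rel_threshold: float = 0.20) -> float:
    """Supra-threshold activation duration of a 100-point profile, in % cycle.

    Threshold = min(h) + ``rel_threshold`` * (max(h) - min(h)); the duration
    is the count of samples strictly above it, which naturally supports
    multi-burst profiles. A flat profile (peak-to-peak < 1e-9) is degenerate:
    duration 0 with a warning.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 1 or h.size != N_CYCLE_POINTS:
        raise InvalidParameterError(f"profile must have {N_CYCLE_POINTS} points")
    ptp = h.max() - h.min()
    if ptp < 1e-9:
        warnings.warn("flat activation profile: duration set to 0", RuntimeWarning, stacklevel=2)
        return 0.0
    thr = h.min() + rel_threshold * ptp
    return float(np.count_nonzero(h > thr))


def activation_metric(d_patient: float, d_healthy: float) -> float:
    """Duration score 1 - |d_p - d_h|/100 for durations in % gait cycle."""
    for d in (d_patient, d_healthy):
        if not 0 <= d <= 100:
            raise InvalidParameterError(f"duration {d} outside [0, 100] % gait cycle")
    return 1.0 - abs(d_patient - d_healthy) / 100.0


def normative_thresholds(metric_values: dict[str, np.ndarray]) -> dict[str, float]:
    """Mean - 2 SD threshold per metric over pooled healthy values.

    Values are pooled across subjects and synergies; the sample SD uses
    ddof=1. At least two values per metric are required.
    """
    out = {}
    for name, values in metric_values.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise InvalidParameterError(
                f"metric '{name}' needs >= 2 healthy values, got {values.size}"
            )
        out[name] = float(values.mean() - 2.0 * values.std(ddof=1))
    return out


def classify_impairment(
    metrics: dict[str, dict[str, float]], thresholds: dict[str, float]
) -> dict[str, bool]:
    """A synergy is impaired iff at least one metric is strictly below its
    threshold; equality passes (not impaired)."""
    flags = {}
    for label, m in metrics.items():
        for name in METRIC_NAMES:
            if name not in m:
                raise InvalidParameterError(f"synergy {label} missing metric '{name}'")
            if name not in thresholds:
                raise InvalidParameterError(f"missing threshold for metric '{name}'")
        flags[label] = any(m[name] < thresholds[name] for name in METRIC_NAMES)
    return flags


@dataclass
class ImpairmentReport:
    """Per-synergy metrics, normative thresholds and impaired flags."""

    labels: list[str]
    metrics: dict[str, dict[str, float]]
    thresholds: dict[str, float]
    impaired: dict[str, bool]
    vaf_fixed_w: float | None = None
    vaf_fixed_h: float | None = None

    @property
    def impaired_labels(self) -> list[str]:
        return [lab for lab in self.labels if self.impaired[lab]]

    def to_frame(self) -> pd.DataFrame:
        """Metrics table: one row per metric, one column per synergy plus the
        threshold column."""
        rows = {}
        for name in METRIC_NAMES:
            rows[name] = {lab: self.metrics[lab][name] for lab in self.labels}
            rows[name]["threshold"] = self.thresholds[name]
        return pd.DataFrame(rows).T[self.labels + ["threshold"]]

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Impairment assessment (mean - 2 SD normative thresholds, strict <)"]
        if self.vaf_fixed_w is not None:
            lines.append(
                f"  NNR VAF: {self.vaf_fixed_w:.2f} (fixed W) / {self.vaf_fixed_h:.2f} (fixed H)"
            )
        lines.append(df.round(2).to_string())
        lines.append("impaired synergies: " + (", ".join(self.impaired_labels) or "none"))
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "metrics": self.metrics,
                "thresholds": self.thresholds,
                "impaired": self.impaired,
                "vaf_fixed_w": self.vaf_fixed_w,
                "vaf_fixed_h": self.vaf_fixed_h,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ImpairmentReport":
        doc = json.loads(text)
        return cls(
            labels=list(doc["labels"]),
            metrics=doc["metrics"],
            thresholds=doc["thresholds"],
            impaired=doc["impaired"],
            vaf_fixed_w=doc.get("vaf_fixed_w"),
            vaf_fixed_h=doc.get("vaf_fixed_h"),
        )


def assess_patient(
    data,
    template: SynergySet,
    thresholds: dict[str, float],
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> ImpairmentReport:
    """Full assessment: both NNR fits, four metrics, threshold classification."""
    recon = TemplateReconstruction(data, template).fit(seed=seed, max_iter=max_iter, tol=tol)
    metrics = recon.metrics()
    flags = classify_impairment(metrics, thresholds)
    return ImpairmentReport(
        labels=list(template.labels),
        metrics=metrics,
        thresholds=dict(thresholds),
        impaired=flags,
        vaf_fixed_w=recon.fixed_w.vaf_total,
        vaf_fixed_h=recon.fixed_h.vaf_total,
    )


def healthy_metric_samples(
    subject_data: list,
    template: SynergySet,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> dict[str, np.ndarray]:
    """Metric values of each healthy subject against the group template,
    pooled across subjects and synergies (input to normative_thresholds)."""
    pooled: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    rng = np.random.default_rng(seed)
    for data in subject_data:
        recon = TemplateReconstruction(data, template).fit(
            seed=int(rng.integers(2**31)), max_iter=max_iter, tol=tol
        )
        for m in recon.metrics().values():
            for name in METRIC_NAMES:
                pooled[name].append(m[name])
    return {name: np.asarray(vals) for name, vals in pooled.items()}
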