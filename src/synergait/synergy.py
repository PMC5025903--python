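"""Muscle-synergy extraction and manipulation.

A muscle synergy is a fixed weighting of muscles (a column of W) recruited by
a time-varying activation profile (a row of H); gait EMG envelopes M
(muscles x time) are decomposed as M ~ W H by NMF. This module provides the
:class:`GaitSynergyModel` / :class:`SynergyResults` pair (fit, order
selection, diagnostics), unit normalization, label-preserving matching
between synergy sets, across-subject averaging, and the similarity /
circular-cross-correlation / lag comparison between walking conditions.

Model-order selection follows the VAF rule used for gait synergies: the
smallest number of synergies whose total VAF exceeds 90%, or beyond which no
single muscle's VAF improves by more than 5 percentage points.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .envelope import EnvelopeStrideSet, N_CYCLE_POINTS
from .errors import DegenerateSynergyError, InvalidParameterError
from .factorization import FactorizationResult, compute_vaf, nmf

CANONICAL_LABELS = ("WA", "PO", "FC", "LD")

__all__ = [
    "SynergySet",
    "GaitSynergyModel",
    "SynergyResults",
    "ConditionComparison",
    "select_model_order",
    "normalize_unit",
    "match_synergies",
    "average_group",
    "compare_conditions",
    "circular_xcorr_max",
    "cosine_similarity",
    "CANONICAL_LABELS",
]


@dataclass
class SynergySet:
    """Weights W (muscles x J) and activation profiles H (J x T).

    T is 100 for a single-cycle template or 100 * n_strides when per-stride
    profiles are concatenated. ``labels`` tags each synergy with its
    biomechanical function (WA, PO, FC, LD) or ``"unlabeled"``.
    """

    muscle_names: list[str]
    W: np.ndarray
    H: np.ndarray
    labels: list[str] = field(default_factory=list)
    vaf_total: float | None = None
    vaf_per_muscle: np.ndarray | None = None
    w_sd: np.ndarray | None = None
    h_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 2 or self.H.ndim != 2 or self.W.shape[1] != self.H.shape[0]:
            raise InvalidParameterError(
                f"inconsistent shapes W{self.W.shape}, H{self.H.shape}"
            )
        if self.W.shape[0] != len(self.muscle_names):
            raise InvalidParameterError("W rows must match muscle_names")
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise InvalidParameterError("W and H must be nonnegative")
        if not self.labels:
            self.labels = ["unlabeled"] * self.W.shape[1]
        if len(self.labels) != self.W.shape[1]:
            raise InvalidParameterError("one label per synergy required")

    @property
    def n_synergies(self) -> int:
        return self.W.shape[1]

    @property
    def n_strides(self) -> int:
        return self.H.shape[1] // N_CYCLE_POINTS

    def mean_profiles(self) -> np.ndarray:
        """J x 100 mean activation profile (mean over concatenated strides)."""
        J, T = self.H.shape
        if T == N_CYCLE_POINTS:
            return self.H.copy()
        if T % N_CYCLE_POINTS:
            raise InvalidParameterError(
                f"H length {T} is not a multiple of {N_CYCLE_POINTS}"
            )
        return self.H.reshape(J, T // N_CYCLE_POINTS, N_CYCLE_POINTS).mean(axis=1)

    def per_stride_profiles(self) -> np.ndarray:
        """J x n_strides x 100 view of the concatenated activation profiles."""
        J, T = self.H.shape
        return self.H.reshape(J, T // N_CYCLE_POINTS, N_CYCLE_POINTS)

    def to_json(self) -> str:
        doc = {
            "muscle_names": self.muscle_names,
            "labels": self.labels,
            "W": self.W.tolist(),
            "H": self.H.tolist(),
            "vaf_total": self.vaf_total,
            "vaf_per_muscle": None if self.vaf_per_muscle is None else np.asarray(self.vaf_per_muscle).tolist(),
            "w_sd": None if self.w_sd is None else np.asarray(self.w_sd).tolist(),
            "h_sd": None if self.h_sd is None else np.asarray(self.h_sd).tolist(),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SynergySet":
        doc = json.loads(text)
        return cls(
            muscle_names=list(doc["muscle_names"]),
            W=np.array(doc["W"], dtype=float),
            H=np.array(doc["H"], dtype=float),
            labels=list(doc["labels"]),
            vaf_total=doc.get("vaf_total"),
            vaf_per_muscle=None if doc.get("vaf_per_muscle") is None else np.array(doc["vaf_per_muscle"]),
            w_sd=None if doc.get("w_sd") is None else np.array(doc["w_sd"]),
            h_sd=None if doc.get("h_sd") is None else np.array(doc["h_sd"]),
        )


def normalize_unit(synergies: SynergySet) -> SynergySet:
    """Scale each weight column to unit Euclidean norm, scaling the matching
    activation row by the old norm so the product W H is unchanged."""
    norms = np.linalg.norm(synergies.W, axis=0)
    if np.any(norms <= 1e-12):
        bad = [synergies.labels[j] for j in np.where(norms <= 1e-12)[0]]
        raise DegenerateSynergyError(f"zero-norm weight column(s): {bad}")
    return SynergySet(
        synergies.muscle_names,
        synergies.W / norms,
        synergies.H * norms[:, None],
        list(synergies.labels),
        vaf_total=synergies.vaf_total,
        vaf_per_muscle=synergies.vaf_per_muscle,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized scalar product; in [0, 1] for nonnegative vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 0 or nb <= 0:
        raise DegenerateSynergyError("cosine similarity undefined for zero vector")
    return float(a @ b / (na * nb))


def circular_xcorr_max(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Maximum centered circular cross-correlation and its signed lag.

    Both profiles are mean-subtracted and the correlation normalized by the
    product of centered norms, so the value lies in [-1, 1]. A positive lag
    means ``b`` is delayed relative to ``a`` (b = roll(a, lag) gives lag);
    lags span [-n/2, n/2-1]. Ties are broken toward the smaller |lag|, then
    toward the negative lag, for determinism.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("profiles must be 1-D and of equal length")
    n = a.size
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na <= 1e-12 or nb <= 1e-12:
        raise DegenerateSynergyError("zero-variance profile in circular cross-correlation")
    # r[l] = sum_t ac[t] * bc[(t + l) mod n]  via FFT-free direct rolls (n=100)
    r = np.array([ac @ np.roll(bc, -l) for l in range(n)]) / (na * nb)
    lags = np.where(np.arange(n) < n - n // 2, np.arange(n), np.arange(n) - n)
    order = np.lexsort((lags, np.abs(lags), -r))
    best = order[0]
    return float(r[best]), int(lags[best])


class GaitSynergyModel:
    """NMF synergy model of per-stride gait EMG envelopes.

    Parameters
    ----------
    data : EnvelopeStrideSet or ndarray
        Either a normalized stride set (strides are concatenated in time to
        form the muscles x (100*n_strides) matrix the factorization sees) or
        a nonnegative matrix directly.
    muscle_names : list of str, optional
        Required when ``data`` is a bare matrix.
    """

    def __init__(self, data, muscle_names: list[str] | None = None):
        if isinstance(data, EnvelopeStrideSet):
            self.endog = data.concatenated()
            self.muscle_names = list(data.muscle_names)
        else:
            self.endog = np.asarray(data, dtype=float)
            if muscle_names is None:
                muscle_names = [f"m{i}" for i in range(self.endog.shape[0])]
            self.muscle_names = list(muscle_names)
        if np.any(self.endog < 0):
            raise InvalidParameterError("envelope matrix must be nonnegative")

    def fit(
        self,
        n_synergies: int | None = None,
        seed: int = 0,
        n_restarts: int = 20,
        max_iter: int = 1000,
        tol: float = 1e-6,
        vaf_threshold: float = 0.90,
        muscle_vaf_gain: float = 0.05,
        j_max: int | None = None,
    ) -> "SynergyResults":
        """Fit the factorization; ``n_synergies=None`` selects the order by
        the VAF rule first."""
        order_flag = False
        if n_synergies is None:
            n_synergies, order_flag = select_model_order(
                self.endog,
                j_max=j_max,
                seed=seed,
                n_restarts=n_restarts,
                max_iter=max_iter,
                tol=tol,
                vaf_threshold=vaf_threshold,
                muscle_vaf_gain=muscle_vaf_gain,
                return_flag=True,
            )
        res = nmf(self.endog, n_synergies, seed=seed, n_restarts=n_restarts,
                  max_iter=max_iter, tol=tol)
        vaf_total, vaf_pm = compute_vaf(self.endog, res.W, res.H)
        synergies = normalize_unit(
            SynergySet(self.muscle_names, res.W, res.H,
                       vaf_total=vaf_total, vaf_per_muscle=vaf_pm)
        )
        return SynergyResults(self, synergies, res, order_warning=order_flag)


class SynergyResults:
    """Fitted synergy decomposition with diagnostics.

    Attributes
    ----------
    synergies : SynergySet
        Unit-normalized weights and their activation profiles.
    fit_result : FactorizationResult
        Raw multiplicative-update output (error history, iterations).
    """

    def __init__(self, model: GaitSynergyModel, synergies: SynergySet,
                 fit_result: FactorizationResult, order_warning: bool = False):
        self.model = model
        self.synergies = synergies
        self.fit_result = fit_result
        self.order_warning = order_warning

    @property
    def vaf_total(self) -> float:
        return self.synergies.vaf_total  # type: ignore[return-value]

    @property
    def vaf_per_muscle(self) -> np.ndarray:
        return self.synergies.vaf_per_muscle  # type: ignore[return-value]

    def match_to(self, reference: SynergySet) -> "SynergyResults":
        """Return results with synergies reordered/labeled against a reference."""
        matched, _, _ = match_synergies(self.synergies, reference)
        return SynergyResults(self.model, matched, self.fit_result, self.order_warning)

    def summary(self) -> str:
        s = self.synergies
        lines = [
            "Gait muscle synergy decomposition (NMF, multiplicative updates)",
            f"  muscles: {len(s.muscle_names)}   synergies: {s.n_synergies}   "
            f"strides: {s.n_strides}",
            f"  total VAF: {s.vaf_total:.4f}   iterations: {self.fit_result.n_iter}"
            + ("   [order rule unsatisfied up to j_max]" if self.order_warning else ""),
            "",
            "  weights (unit-norm columns):",
        ]
        header = "    {:<8s}".format("muscle") + "".join(f"{lab:>8s}" for lab in s.labels)
        lines.append(header)
        for i, name in enumerate(s.muscle_names):
            lines.append("    {:<8s}".format(name) + "".join(f"{w:8.3f}" for w in s.W[i]))
        lines.append("")
        lines.append("  per-muscle VAF: " + "  ".join(
            f"{n}={v:.3f}" for n, v in zip(s.muscle_names, s.vaf_per_muscle)))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar-plot weights and line-plot mean activation profiles."""
        import matplotlib.pyplot as plt

        s = self.synergies
        J = s.n_synergies
        fig, axes = plt.subplots(J, 2, figsize=(8, 2 * J), squeeze=False)
        profiles = s.mean_profiles()
        x = np.arange(len(s.muscle_names))
        for j in range(J):
            axes[j, 0].bar(x, s.W[:, j])
            axes[j, 0].set_xticks(x, s.muscle_names, rotation=45, fontsize=7)
            axes[j, 0].set_ylabel(s.labels[j])
            axes[j, 1].plot(profiles[j])
            axes[j, 1].set_xlim(0, N_CYCLE_POINTS - 1)
        axes[-1, 1].set_xlabel("% gait cycle")
        fig.tight_layout()
        return fig


def select_model_order(
    M: np.ndarray,
    j_max: int | None = None,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
    vaf_threshold: float = 0.90,
    muscle_vaf_gain: float = 0.05,
    return_flag: bool = False,
):
    """Smallest synergy count J whose total VAF exceeds ``vaf_threshold``, or
    past which adding a synergy improves no single muscle's VAF by more than
    ``muscle_vaf_gain``.

    Evaluation ascends J = 1, 2, ...; if neither clause is met up to
    ``j_max`` (default: number of muscles), ``j_max`` is returned with a
    warning (and flag when ``return_flag``).
    """
    M = np.asarray(M, dtype=float)
    n_muscles = M.shape[0]
    if j_max is None:
        j_max = n_muscles
    j_max = min(j_max, min(M.shape))

    fits: dict[int, tuple[float, np.ndarray]] = {}

    def vaf_at(j: int) -> tuple[float, np.ndarray]:
        if j not in fits:
            res = nmf(M, j, seed=seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol)
            fits[j] = compute_vaf(M, res.W, res.H)
        return fits[j]

    chosen, flag = j_max, True
    for j in range(1, j_max + 1):
        total, per_muscle = vaf_at(j)
        if total > vaf_threshold:
            chosen, flag = j, False
            break
        if j < j_max:
            _, per_next = vaf_at(j + 1)
            gains = per_next - per_muscle
            if np.nanmax(gains) <= muscle_vaf_gain:
                chosen, flag = j, False
                break
    if flag:
        warnings.warn(
            f"no synergy count up to {j_max} satisfied the VAF order rule; returning {j_max}",
            RuntimeWarning,
            stacklevel=2,
        )
    return (chosen, flag) if return_flag else chosen


def match_synergies(
    candidate: SynergySet, reference: SynergySet
) -> tuple[SynergySet, np.ndarray, np.ndarray]:
    """Assign candidate synergies one-to-one to reference synergies,
    maximizing total weight-cosine similarity.

    Returns the reordered candidate (labels inherited from the reference),
    the assignment (``assignment[k]`` = candidate index matched to reference
    synergy k, -1 where the reference synergy is unmatched) and the per-pair
    cosines. Ties are resolved deterministically by synergy index.
    """
    if list(candidate.muscle_names) != list(reference.muscle_names):
        raise InvalidParameterError(
            f"muscle sets differ: {candidate.muscle_names} vs {reference.muscle_names}"
        )
    Jc, Jr = candidate.n_synergies, reference.n_synergies
    if Jc > Jr:
        raise InvalidParameterError("candidate has more synergies than reference")
    sim = np.zeros((Jr, Jc))
    for r in range(Jr):
        for c in range(Jc):
            sim[r, c] = cosine_similarity(reference.W[:, r], candidate.W[:, c])
    rows, cols = linear_sum_assignment(-sim)
    assignment = np.full(Jr, -1, dtype=int)
    assignment[rows] = cols
    matched_refs = [r for r in range(Jr) if assignment[r] >= 0]
    order = [assignment[r] for r in matched_refs]
    cosines = np.array([sim[r, assignment[r]] for r in matched_refs])
    matched = SynergySet(
        candidate.muscle_names,
        candidate.W[:, order],
        candidate.H[order, :],
        [reference.labels[r] for r in matched_refs],
        vaf_total=candidate.vaf_total,
        vaf_per_muscle=candidate.vaf_per_muscle,
    )
    return matched, assignment, cosines


def match_synergies_bruteforce(candidate: SynergySet, reference: SynergySet) -> np.ndarray:
    """Exhaustive-permutation assignment (oracle for small J)."""
    Jc, Jr = candidate.n_synergies, reference.n_synergies
    sim = np.array([
        [cosine_similarity(reference.W[:, r], candidate.W[:, c]) for c in range(Jc)]
        for r in range(Jr)
    ])
    best_total, best_assign = -np.inf, None
    for refs in itertools.permutations(range(Jr), Jc):
        total = sum(sim[r, c] for c, r in enumerate(refs))
        if total > best_total + 1e-15:
            best_total = total
            assign = np.full(Jr, -1, dtype=int)
            for c, r in enumerate(refs):
                assign[r] = c
            best_assign = assign
    return best_assign


def average_group(
    synergy_sets: list[SynergySet], reference: SynergySet
) -> SynergySet:
    """Across-subject average synergy set.

    Each subject's set is matched to the reference and unit-normalized, then
    W and the mean activation profiles are averaged elementwise; the averaged
    W is re-normalized to unit columns (H scaled to preserve the product).
    Per-entry standard deviations are retained in ``w_sd`` / ``h_sd``.
    """
    if not synergy_sets:
        raise InvalidParameterError("no synergy sets to average")
    matched_W, matched_H = [], []
    J = None
    for s in synergy_sets:
        m, assignment, _ = match_synergies(normalize_unit(s), reference)
        if J is None:
            J = m.n_synergies
        elif m.n_synergies != J:
            raise InvalidParameterError(
                f"inconsistent synergy count after matching: {m.n_synergies} vs {J}"
            )
        matched_W.append(m.W)
        matched_H.append(m.mean_profiles())
    Wm = np.mean(matched_W, axis=0)
    Hm = np.mean(matched_H, axis=0)
    out = normalize_unit(
        SynergySet(reference.muscle_names, Wm, Hm, list(reference.labels[:J]))
    )
    out.w_sd = np.std(matched_W, axis=0, ddof=1) if len(matched_W) > 1 else np.zeros_like(Wm)
    out.h_sd = np.std(matched_H, axis=0, ddof=1) if len(matched_H) > 1 else np.zeros_like(Hm)
    return out


@dataclass
class ConditionComparison:
    """Per-synergy comparison between two walking conditions."""

    labels: list[str]
    similarity: np.ndarray
    correlation: np.ndarray
    lag: np.ndarray  # % gait cycle, integer in [-50, 49]
    similarity_mean: float = 0.0
    similarity_sd: float = 0.0
    correlation_mean: float = 0.0
    correlation_sd: float = 0.0
    lag_mean: float = 0.0
    lag_sd: float = 0.0

    def summary(self) -> str:
        lines = ["Condition comparison (weights similarity / profile xcorr / lag %):"]
        for j, lab in enumerate(self.labels):
            lines.append(
                f"  {lab}: similarity={self.similarity[j]:.3f} "
                f"correlation={self.correlation[j]:.3f} lag={self.lag[j]:+d}"
            )
        lines.append(
            f"  mean(SD): similarity {self.similarity_mean:.2f} ({self.similarity_sd:.2f}), "
            f"correlation {self.correlation_mean:.2f} ({self.correlation_sd:.2f}), "
            f"lag {self.lag_mean:.1f} ({self.lag_sd:.1f})"
        )
        return "\n".join(lines)


def compare_conditions(set_a: SynergySet, set_b: SynergySet) -> ConditionComparison:
    """Similarity, max circular cross-correlation and lag between two matched
    synergy sets (e.g. overground vs treadmill). Positive lag: B delayed."""
    if set_a.n_synergies != set_b.n_synergies:
        raise InvalidParameterError("synergy counts differ")
    pa, pb = set_a.mean_profiles(), set_b.mean_profiles()
    if pa.shape[1] != N_CYCLE_POINTS or pb.shape[1] != N_CYCLE_POINTS:
        raise InvalidParameterError(f"profiles must have {N_CYCLE_POINTS} points")
    sims, corrs, lags = [], [], []
    for j in range(set_a.n_synergies):
        sims.append(cosine_similarity(set_a.W[:, j], set_b.W[:, j]))
        r, lag = circular_xcorr_max(pa[j], pb[j])
        corrs.append(r)
        lags.append(lag)
    sims_a, corrs_a, lags_a = np.array(sims), np.array(corrs), np.array(lags)
    ddof = 1 if len(sims) > 1 else 0
    return ConditionComparison(
        labels=list(set_a.labels),
        similarity=sims_a,
        correlation=corrs_a,
        lag=lags_a,
        similarity_mean=float(sims_a.mean()), similarity_sd=float(sims_a.std(ddof=ddof)),
        correlation_mean=float(corrs_a.mean()), correlation_sd=float(corrs_a.std(ddof=ddof)),
        lag_mean=float(lags_a.mean()), lag_sd=float(lags_a.std(ddof=ddof)),
    )
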