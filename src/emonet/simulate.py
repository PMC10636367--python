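"""Synthetic cohorts with stationary VAR(1) emotion dynamics.

Every participant follows x_t = c + A(gamma) x_{t-1} + eps_t, with the
off-diagonal lag coefficients and the off-diagonal innovation covariances
both scaled by a per-person connectivity multiplier gamma.  Weekly
depression sum scores are coupled to the weekly mean of the negative-affect
items, so a between-person gamma gradient induces a gradient in depression
variability — the structure the downstream analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import Cohort, DepressionSeries, EmaPanel

__all__ = [
    "Design",
    "DepressionLink",
    "GenerativeSpec",
    "SimulatedCohort",
    "DESIGNS",
    "make_spec",
    "simulate_participant",
    "simulate_cohort",
    "scale_lag_matrix",
    "scale_innovation_cov",
    "partial_correlations",
    "SimulationError",
]

BURN_IN = 200
_SPECTRAL_CAP = 0.95  # stationarity margin enforced at gamma_max
_GAMMA_CAP = 3.0


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Design:
    """Assessment schedule of a study arm."""

    assessments_per_day: int
    n_days: int
    hours_between: float
    scale: str

    @property
    def n_assessments(self) -> int:
        return self.assessments_per_day * self.n_days

    @property
    def per_week(self) -> int:
        return self.assessments_per_day * 7

    @property
    def n_weeks(self) -> int:
        return self.n_days // 7


#: ``neureka``: 2/day x 56 d, 12-h spacing, 7-point Likert.
#: ``hnatd``:   3/day x 30 d,  6-h spacing, VAS 0-100.
DESIGNS: dict[str, Design] = {
    "neureka": Design(2, 56, 12.0, "likert"),
    "hnatd": Design(3, 30, 6.0, "vas"),
}


@dataclass(frozen=True)
class DepressionLink:
    """Weekly score = round(clip(a + b * mean weekly negative affect + noise)).

    The default offset sits low enough that the 0-floor induces mild
    positive skew, so participants with more variable affect also score
    somewhat higher on average — the mean-variance confounding that the
    control regression is designed to pick apart.
    """

    a: float = 10.0
    b: float = 9.0
    noise_sd: float = 1.5


@dataclass
class GenerativeSpec:
    """Population parameters of the simulated VAR(1) process.

    ``A0`` is the template lag matrix; for a participant with multiplier
    gamma, the off-diagonal entries of ``A0`` are scaled by gamma while the
    autoregressive diagonal is kept.  ``S0`` (innovation covariance) is
    scaled the same way, so contemporaneous coupling tracks gamma too.
    """

    n_items: int
    item_names: list[str]
    item_valence: dict[str, str]
    A0: np.ndarray
    S0: np.ndarray
    gamma_range: tuple[float, float]
    intercepts: np.ndarray
    depression_link: DepressionLink = field(default_factory=DepressionLink)
    missing_rate: float = 0.0
    scale: str = "likert"
    design: Design = field(default_factory=lambda: DESIGNS["neureka"])

    def validate(self) -> None:
        lo, hi = self.gamma_range
        if not (0 <= lo <= hi):
            raise SimulationError("gamma_range must satisfy 0 <= lo <= hi")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")
        for g in (lo, hi):
            if _spectral_radius(scale_lag_matrix(self.A0, g)) >= 1:
                raise SimulationError(f"A(gamma={g:g}) is not stationary")
            if np.linalg.eigvalsh(scale_innovation_cov(self.S0, g)).min() <= 0:
                raise SimulationError(f"S(gamma={g:g}) is not positive definite")


@dataclass
class SimulatedCohort:
    """A cohort plus the ground truth used to simulate it."""

    cohort: Cohort
    true_gamma: dict[str, float]
    true_lag: dict[str, np.ndarray]
    true_partial: dict[str, np.ndarray]
    spec: GenerativeSpec


# -- parameter helpers -----------------------------------------------------


def scale_lag_matrix(A0: np.ndarray, gamma: float) -> np.ndarray:
    """Off-diagonal entries times gamma; diagonal kept."""
    A = np.asarray(A0, dtype=float) * gamma
    np.fill_diagonal(A, np.diag(A0))
    return A


def scale_innovation_cov(S0: np.ndarray, gamma: float) -> np.ndarray:
    S = np.asarray(S0, dtype=float) * gamma
    np.fill_diagonal(S, np.diag(S0))
    return S


def partial_correlations(cov: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of a covariance (zero diagonal)."""
    P = np.linalg.inv(cov)
    d = np.sqrt(np.diag(P))
    pc = -P / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return (pc + pc.T) / 2


def _spectral_radius(A: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(A)).max())


#: Cross-valence couplings are weaker than within-valence ones, so the
#: *signed* edge sum of the template is positive and overall connectivity
#: grows with gamma (as in empirical affect networks, where reinforcement
#: within valence dominates opposition across valence).
CROSS_VALENCE_WEIGHT = 0.35


def _valence_signs(valence: np.ndarray) -> np.ndarray:
    """+1 for same-valence pairs, -1 for mixed pairs.

    Mirrors the empirical structure of affect networks: negative emotions
    reinforce each other and oppose positive ones.
    """
    s = np.where(valence == "negative", -1.0, 1.0)
    return np.outer(s, s)


def _valence_weights(valence: np.ndarray) -> np.ndarray:
    signs = _valence_signs(valence)
    return np.where(signs > 0, 1.0, CROSS_VALENCE_WEIGHT)


def make_spec(
    n_items: int,
    base_coupling: float,
    seed: int,
    *,
    n_negative: int | None = None,
    design: Design | str = "neureka",
    missing_rate: float = 0.0,
    scale: str | None = None,
    depression_link: DepressionLink | None = None,
    contemporaneous_coupling: float = 0.25,
) -> GenerativeSpec:
    """Build a stationarity-checked generative spec.

    The template lag matrix has autoregressive diagonal around 0.3 and
    valence-signed off-diagonal couplings of magnitude ~``base_coupling``.
    ``gamma_range`` is the largest interval [0, gamma_max] on which both
    the scaled lag matrix stays stationary and the scaled innovation
    covariance stays positive definite (verified on a dense grid).
    """
    if n_items < 1:
        raise SimulationError("n_items must be >= 1")
    if base_coupling < 0:
        raise SimulationError("base_coupling must be >= 0")
    if isinstance(design, str):
        design = DESIGNS[design]
    if n_negative is None:
        n_negative = max(1, round(n_items * 9 / 16))
    n_negative = min(n_negative, n_items)
    rng = np.random.default_rng(seed)

    names = [f"neg{i + 1:02d}" for i in range(n_negative)] + [
        f"pos{i + 1:02d}" for i in range(n_items - n_negative)
    ]
    valence = np.array(
        ["negative"] * n_negative + ["positive"] * (n_items - n_negative)
    )
    signs = _valence_signs(valence)
    weights = _valence_weights(valence)

    A0 = signs * weights * base_coupling * rng.uniform(0.5, 1.5, size=(n_items, n_items))
    np.fill_diagonal(A0, rng.uniform(0.25, 0.35, size=n_items))

    # Innovation covariance: unit variances, valence-signed correlations,
    # shrunk toward identity until comfortably positive definite.
    R = signs * weights * contemporaneous_coupling * rng.uniform(
        0.5, 1.0, size=(n_items, n_items)
    )
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    off = R - np.diag(np.diag(R))
    w = 1.0
    while np.linalg.eigvalsh(np.eye(n_items) + w * off).min() < 0.05 and w > 1e-3:
        w *= 0.8
    S0 = np.eye(n_items) + w * off

    grid = np.linspace(0.0, _GAMMA_CAP, 121)
    gamma_max = 0.0
    for g in grid[1:]:
        ok = _spectral_radius(scale_lag_matrix(A0, g)) < _SPECTRAL_CAP and (
            np.linalg.eigvalsh(scale_innovation_cov(S0, g)).min() > 1e-8
        )
        if not ok:
            break
        gamma_max = float(g)
    if gamma_max <= 0:
        raise SimulationError(
            "no gamma_max > 0 satisfies stationarity for this template"
        )

    spec = GenerativeSpec(
        n_items=n_items,
        item_names=names,
        item_valence=dict(zip(names, valence)),
        A0=A0,
        S0=S0,
        gamma_range=(0.0, gamma_max),
        intercepts=np.zeros(n_items),
        depression_link=depression_link or DepressionLink(),
        missing_rate=missing_rate,
        scale=scale if scale is not None else design.scale,
        design=design,
    )
    spec.validate()
    return spec


# -- simulation ------------------------------------------------------------


def _simulate_latent(
    spec: GenerativeSpec, gamma: float, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Raw (continuous, complete) VAR(1) path after burn-in discard."""
    A = scale_lag_matrix(spec.A0, gamma)
    S = scale_innovation_cov(spec.S0, gamma)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise SimulationError(f"S(gamma={gamma:g}) not positive definite") from exc
    c = np.asarray(spec.intercepts, dtype=float)
    total = BURN_IN + n_steps
    eps = rng.standard_normal((total, spec.n_items)) @ L.T
    x = np.empty((total, spec.n_items))
    x[0] = c + eps[0]
    for t in range(1, total):
        x[t] = c + A @ x[t - 1] + eps[t]
    if not np.all(np.isfinite(x)):
        raise SimulationError("non-finite draw during simulation")
    return x[BURN_IN:]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _to_scale(latent: np.ndarray, scale: str) -> np.ndarray:
    """Map the latent continuous path onto the declared response scale.

    Likert: round half away from zero, clip to [-3, 3].
    VAS: affine map of [-3, 3] onto [0, 100], then clip.
    """
    if scale == "continuous":
        return latent
    if scale == "likert":
        return np.clip(_round_half_away(latent), -3, 3)
    if scale == "vas":
        return np.clip((latent + 3.0) / 6.0 * 100.0, 0.0, 100.0)
    raise SimulationError(f"unknown scale {scale!r}")


def simulate_participant(
    spec: GenerativeSpec, gamma: float, T: int, seed: int
) -> EmaPanel:
    """Simulate one participant's panel of ``T`` assessments.

    A burn-in of 200 steps is discarded, values are mapped to the declared
    scale, and MCAR missingness is applied cell-wise at ``missing_rate``.
    """
    lo, hi = spec.gamma_range
    if not lo <= gamma <= hi:
        raise SimulationError(
            f"gamma={gamma:g} outside gamma_range [{lo:g}, {hi:g}]"
        )
    if T < 2:
        raise SimulationError("T must be >= 2")
    rng = np.random.default_rng(seed)
    latent = _simulate_latent(spec, gamma, T, rng)
    values = _to_scale(latent, spec.scale)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)
    return EmaPanel(
        participant_id=f"sim{seed}",
        item_names=list(spec.item_names),
        item_valence=dict(spec.item_valence),
        values=values,
        scale=spec.scale,
        spacing_hours=spec.design.hours_between,
    )


def simulate_cohort(
    spec: GenerativeSpec, n_participants: int, seed: int
) -> SimulatedCohort:
    """Simulate a full cohort under the spec's design.

    Per participant: gamma drawn uniformly from ``gamma_range``; a panel of
    ``design.n_assessments`` slots; weekly depression scores computed from
    the weekly mean of negative items (baseline from an extra pre-study
    week carved out after burn-in).  Ground truth is retained.
    """
    if n_participants < 1:
        raise SimulationError("n_participants must be >= 1")
    design = spec.design
    T = design.n_assessments
    per_week = design.per_week
    n_weeks = design.n_weeks
    if n_weeks >= 1 and per_week < 2:
        raise SimulationError("design gives < 2 assessments per week")

    link = spec.depression_link
    rng = np.random.default_rng(seed)
    neg_idx = [
        i for i, name in enumerate(spec.item_names)
        if spec.item_valence[name] == "negative"
    ]

    cohort = Cohort(design_label=f"simulated:{spec.scale}")
    true_gamma: dict[str, float] = {}
    true_lag: dict[str, np.ndarray] = {}
    true_partial: dict[str, np.ndarray] = {}

    for i in range(n_participants):
        pid = f"p{i + 1:04d}"
        gamma = float(rng.uniform(*spec.gamma_range))
        latent = _simulate_latent(spec, gamma, per_week + T, rng)
        scaled = _to_scale(latent, spec.scale)
        pre_week, study = scaled[:per_week], scaled[per_week:]

        # depression: baseline from the pre-study week, then one score per
        # study week, each driven by that week's mean negative affect
        scores = np.full(1 + n_weeks, np.nan)
        segments = [pre_week] + [
            study[w * per_week : (w + 1) * per_week] for w in range(n_weeks)
        ]
        for w, seg in enumerate(segments):
            m = seg[:, neg_idx].mean() if neg_idx else 0.0
            raw = link.a + link.b * m + link.noise_sd * rng.standard_normal()
            scores[w] = _round_half_away(np.clip(raw, 0.0, 60.0))

        values = study.copy()
        if spec.missing_rate > 0:
            mask = rng.random(values.shape) < spec.missing_rate
            values = np.where(mask, np.nan, values)

        cohort.panels[pid] = EmaPanel(
            participant_id=pid,
            item_names=list(spec.item_names),
            item_valence=dict(spec.item_valence),
            values=values,
            scale=spec.scale,
            spacing_hours=design.hours_between,
        )
        cohort.depression[pid] = DepressionSeries(participant_id=pid, scores=scores)
        true_gamma[pid] = gamma
        true_lag[pid] = scale_lag_matrix(spec.A0, gamma)
        true_partial[pid] = partial_correlations(scale_innovation_cov(spec.S0, gamma))

    return SimulatedCohort(
        cohort=cohort,
        true_gamma=true_gamma,
        true_lag=true_lag,
        true_partial=true_partial,
        spec=spec,
    )
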