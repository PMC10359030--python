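"""Synthetic subjects and sessions for the interval-timing paradigm.

Emulates the two behavioral tasks end to end so every analysis stage can be
exercised without human data:

* Interval reproduction ("Ready-Set-Go"): four uniform prior conditions —
  narrow-short (NS, 0.5–0.9 s), narrow-medium (NM, 0.7–1.1 s), narrow-long
  (NL, 0.9–1.3 s) and wide-medium (WM, 0.5–1.3 s) — each run as three blocks
  of six repetitions per stimulus bin (972 trials per session).  Positive
  feedback uses an adaptive one-up/one-down window whose width is
  proportional to the sample interval with coefficient ``k``.

* Temporal categorization: 59-trial 2IFC sessions (50 QUEST-placed probes
  plus 9 uniform fillers) against the fixed 0.9 s reference.

Simulated subjects are BLS observers (see :mod:`priortime.observer`) with a
Weber fraction drawn from a truncated log-normal matching the empirically
reported range (0.03–0.37, mean ~0.12), a zero-inflated right-skewed
hallucination-proneness (CAPS) score (~60% zeros), and a prior-compression
fraction tied to CAPS rank — the generative link the interindividual
analyses are meant to recover.  An optional exponential prior-adaptation
rate produces start/transition nonstationarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .observer import (
    ObserverParams,
    PriorSpec,
    _draw_production,
    bls_estimate,
    compress_uniform_prior,
)
from . import psychometrics as psy

__all__ = [
    "ConditionSpec",
    "SessionPlan",
    "FeedbackController",
    "SubjectProfile",
    "PopulationHyper",
    "standard_conditions",
    "plan_session",
    "feedback_step",
    "simulate_session",
    "generate_population",
    "run_categorization_session",
    "write_trials",
    "read_trials",
    "REPRODUCTION_COLUMNS",
    "CATEGORIZATION_COLUMNS",
    "COVARIATE_COLUMNS",
]

CONDITION_BOUNDS = {
    "NS": (0.5, 0.9, 11),
    "NM": (0.7, 1.1, 11),
    "NL": (0.9, 1.3, 11),
    "WM": (0.5, 1.3, 21),
}

#: training-block trial counts: one block, 4 reps/bin narrow, 2 reps/bin wide
TRAINING_TRIALS = {"narrow": 4 * 11, "wide": 2 * 21}


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    prior: PriorSpec
    reps_per_bin_per_block: int = 6
    n_blocks: int = 3

    @property
    def trials_per_block(self) -> int:
        return self.prior.n_bins * self.reps_per_bin_per_block

    @property
    def total_trials(self) -> int:
        return self.trials_per_block * self.n_blocks


def standard_conditions(reps_per_bin_per_block: int = 6, n_blocks: int = 3) -> dict[str, ConditionSpec]:
    """The four prior conditions with their binned uniform stimulus sets."""
    out = {}
    for name, (lo, hi, nb) in CONDITION_BOUNDS.items():
        out[name] = ConditionSpec(
            name=name,
            prior=PriorSpec(family="uniform", lower_s=lo, upper_s=hi, n_bins=nb),
            reps_per_bin_per_block=reps_per_bin_per_block,
            n_blocks=n_blocks,
        )
    return out


@dataclass(frozen=True)
class SessionPlan:
    """Ordered (condition, block) schedule for one session."""

    order: tuple[str, ...]  # condition order, e.g. ("WM", "NM", "NS", "NL")
    blocks: tuple[tuple[str, int], ...]
    seed: int | None = None


_NARROW_PERMS = list(itertools.permutations(["NS", "NM", "NL"]))
#: the 12 schedules allowed by the design: WM all-first or all-last, narrow
#: conditions contiguous in any order
VALID_ORDERS = [("WM",) + p for p in _NARROW_PERMS] + [p + ("WM",) for p in _NARROW_PERMS]


def plan_session(seed: int | np.random.Generator, n_blocks: int = 3) -> SessionPlan:
    """Draw one of the 12 valid condition orders uniformly at random."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = VALID_ORDERS[rng.integers(len(VALID_ORDERS))]
    blocks = tuple((c, b) for c in order for b in range(1, n_blocks + 1))
    return SessionPlan(order=order, blocks=blocks,
                       seed=seed if isinstance(seed, int) else None)


@dataclass(frozen=True)
class FeedbackController:
    """One-up/one-down adaptive feedback window, width = k * t_s."""

    k: float = 0.1
    k0: float = 0.1
    step: float = 0.015


def feedback_step(
    ctrl: FeedbackController, ts: float, tp: float
) -> tuple[bool, FeedbackController]:
    """Score one trial and adapt the window coefficient.

    A hit is a production within half the window of the sample
    (``|tp - ts| <= k * ts / 2``); ``k`` shrinks by ``step`` on a hit and
    grows by ``step`` on a miss, floored at ``step`` so the window never
    vanishes.  The one-up/one-down rule equilibrates at ~50% hits.
    """
    if ts <= 0:
        raise ValueError("ts must be > 0")
    hit = abs(tp - ts) <= ctrl.k * ts / 2
    k_new = ctrl.k - ctrl.step if hit else ctrl.k + ctrl.step
    k_new = max(k_new, ctrl.step)
    return hit, replace(ctrl, k=k_new)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    observer: ObserverParams
    caps_score: int = 0
    adaptation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.caps_score < 0:
            raise ValueError("caps_score must be >= 0")
        if not 0 <= self.adaptation_rate < 1:
            raise ValueError("adaptation_rate must lie in [0, 1)")


@dataclass(frozen=True)
class PopulationHyper:
    """Hyperparameters of the synthetic population.

    Weber fractions are log-normal (median ``wm_median``, log-SD
    ``wm_log_sd``) truncated to ``wm_range`` by resampling.  CAPS scores are
    zero-inflated (P(0) = ``caps_p_zero``) with a right-skewed log-normal
    positive part rounded to integers.  The prior-compression fraction of
    subject i is ``gamma_max`` times the rank-normalized CAPS score (zeros
    map to 0).  ``adaptation_rate`` applies to every subject.
    """

    wm_median: float = 0.11
    wm_log_sd: float = 0.5
    wm_range: tuple[float, float] = (0.03, 0.37)
    caps_p_zero: float = 0.6
    caps_log_mean: float = 3.5
    caps_log_sd: float = 0.9
    caps_max: int = 512
    gamma_max: float = 0.1
    wp: float = 0.1
    adaptation_rate: float = 0.0


def generate_population(
    n: int, hyper: PopulationHyper | None = None, seed: int | np.random.Generator = 0
) -> list[SubjectProfile]:
    """Draw ``n`` independent subjects; WF and CAPS are generated independently."""
    if n < 1:
        raise ValueError("n must be >= 1")
    hyper = hyper or PopulationHyper()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    lo, hi = hyper.wm_range
    wm = np.exp(rng.normal(np.log(hyper.wm_median), hyper.wm_log_sd, size=n))
    for _ in range(1000):
        bad = (wm < lo) | (wm > hi)
        if not bad.any():
            break
        wm[bad] = np.exp(rng.normal(np.log(hyper.wm_median), hyper.wm_log_sd, bad.sum()))
    wm = np.clip(wm, lo, hi)

    zero = rng.random(n) < hyper.caps_p_zero
    caps = np.where(
        zero,
        0,
        np.minimum(
            np.round(np.exp(rng.normal(hyper.caps_log_mean, hyper.caps_log_sd, n))),
            hyper.caps_max,
        ),
    ).astype(int)

    gamma = caps_to_gamma(caps, hyper.gamma_max)
    return [
        SubjectProfile(
            subject_id=f"S{i:03d}",
            observer=ObserverParams(wm=float(wm[i]), wp=hyper.wp, compression=float(gamma[i])),
            caps_score=int(caps[i]),
            adaptation_rate=hyper.adaptation_rate,
        )
        for i in range(n)
    ]


def caps_to_gamma(caps: np.ndarray, gamma_max: float) -> np.ndarray:
    """Map CAPS scores to prior-compression fractions by rank normalization.

    Ranks (ties at the minimum) are rescaled to [0, 1] across the population
    and multiplied by ``gamma_max``, making the link robust to the heavy
    right skew of the score distribution; every zero score — the population
    minimum — maps to gamma = 0, and the highest score to ``gamma_max``.
    """
    from scipy.stats import rankdata

    caps = np.asarray(caps)
    if len(caps) < 2 or caps.min() == caps.max():
        return np.zeros(len(caps), dtype=float)
    ranks = rankdata(caps, method="min")
    return gamma_max * (ranks - 1) / (len(caps) - 1)


# ---------------------------------------------------------------------------
# Interval-reproduction session
# ---------------------------------------------------------------------------


def _effective_prior(profile: SubjectProfile, cond: ConditionSpec) -> PriorSpec:
    """The observer's internal prior: the condition prior, compressed for WM."""
    if cond.name == "WM" and profile.observer.compression > 0:
        return compress_uniform_prior(cond.prior, profile.observer.compression)
    return cond.prior


def simulate_session(
    profile: SubjectProfile,
    plan: SessionPlan,
    seed: int | np.random.Generator = 0,
    conditions: dict[str, ConditionSpec] | None = None,
) -> pd.DataFrame:
    """Simulate one full reproduction session as a tidy trial table.

    Stimuli in each block are a random permutation of (bins x repetitions).
    The observer's estimate uses the condition's prior (WM compressed by the
    subject's gamma); with a positive adaptation rate the subjective prior's
    mean and half-width are instead updated exponentially toward the observed
    samples after every trial, which produces start- and transition-related
    slope shifts.  Feedback only adapts the window coefficient ``k``; it
    never alters behavior.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    conditions = conditions or standard_conditions()
    obs = profile.observer
    lam = profile.adaptation_rate

    records: list[dict] = []
    ctrl = FeedbackController()
    trial_index = 0
    # adaptive subjective prior state: mean and half-width, initialized to
    # the full stimulus range (an agnostic starting belief)
    m, h = 0.9, 0.4

    for cond_name, block in plan.blocks:
        cond = conditions[cond_name]
        bins = cond.prior.bin_values()
        ts = rng.permutation(np.repeat(bins, cond.reps_per_bin_per_block))
        tm = rng.normal(ts, obs.wm * ts)

        if lam == 0:
            prior = _effective_prior(profile, cond)
            te = bls_estimate(tm, prior, obs.wm)
        else:
            te = np.empty_like(tm)
            for i in range(len(ts)):
                lo = max(m - h, 0.05)
                hi = max(m + h, lo + 0.02)
                prior = PriorSpec(family="uniform", lower_s=lo, upper_s=hi)
                if cond_name == "WM" and obs.compression > 0:
                    prior = compress_uniform_prior(prior, obs.compression)
                te[i] = bls_estimate(float(tm[i]), prior, obs.wm)
                m += lam * (ts[i] - m)
                h = (1 - lam) * h + lam * 2.0 * abs(ts[i] - m)

        tp = _draw_production(te, obs.wp, rng)

        for i in range(len(ts)):
            k_now = ctrl.k
            hit, ctrl = feedback_step(ctrl, float(ts[i]), float(tp[i]))
            records.append(
                {
                    "subject_id": profile.subject_id,
                    "condition": cond_name,
                    "block": block,
                    "trial_index": trial_index,
                    "sample_s": float(ts[i]),
                    "production_s": float(tp[i]),
                    "hit": bool(hit),
                    "k_at_trial": float(k_now),
                }
            )
            trial_index += 1

    return pd.DataFrame.from_records(records, columns=REPRODUCTION_COLUMNS)


# ---------------------------------------------------------------------------
# Temporal-categorization session
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorizationConfig:
    n_staircase: int = 50
    n_filler: int = 9
    reference_s: float = psy.REFERENCE_S


def run_categorization_session(
    profile: SubjectProfile,
    config: CategorizationConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one 2IFC session: QUEST probes plus uniform fillers.

    Probe intervals come from the QUEST posterior-mean placement; filler
    trials are drawn uniformly on the stimulus range and interleaved at
    random positions.  Responses follow the scalar-variability 2IFC observer
    with the subject's Weber fraction.
    """
    config = config or CategorizationConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_total = config.n_staircase + config.n_filler
    filler_pos = set(rng.choice(n_total, size=config.n_filler, replace=False).tolist())

    state = psy.quest_init()
    wm = profile.observer.wm
    rows = []
    for t in range(n_total):
        if t in filler_pos:
            i2 = float(rng.uniform(psy.STIM_LO, psy.STIM_HI))
            source = "uniform_filler"
        else:
            i2 = float(np.clip(state.next_stimulus_s, psy.STIM_LO, psy.STIM_HI))
            source = "staircase"
        p2 = psy.p_choose_interval2(config.reference_s, i2, wm)
        resp2 = bool(rng.random() < p2)
        if source == "staircase":
            state = psy.quest_update(state, i2, resp2)
        rows.append(
            {
                "subject_id": profile.subject_id,
                "trial_index": t,
                "interval1_s": config.reference_s,
                "interval2_s": i2,
                "response": "interval2_longer" if resp2 else "interval1_longer",
                "source": source,
            }
        )
    return pd.DataFrame.from_records(rows, columns=CATEGORIZATION_COLUMNS)


# ---------------------------------------------------------------------------
# CSV I/O with schema validation
# ---------------------------------------------------------------------------

REPRODUCTION_COLUMNS = [
    "subject_id", "condition", "block", "trial_index",
    "sample_s", "production_s", "hit", "k_at_trial",
]
CATEGORIZATION_COLUMNS = [
    "subject_id", "trial_index", "interval1_s", "interval2_s", "response", "source",
]
COVARIATE_COLUMNS = ["subject_id", "wf_true", "caps"]

_SCHEMAS = {
    "reproduction": REPRODUCTION_COLUMNS,
    "categorization": CATEGORIZATION_COLUMNS,
    "covariates": COVARIATE_COLUMNS,
}
_FLOAT_COLUMNS = {
    "reproduction": ["sample_s", "production_s", "k_at_trial"],
    "categorization": ["interval1_s", "interval2_s"],
    "covariates": ["wf_true"],
}


class SchemaError(ValueError):
    """Raised when a trial table violates its declared CSV schema."""


def write_trials(df: pd.DataFrame, path, kind: str = "reproduction") -> None:
    """Write a trial table as UTF-8 CSV with '.' decimals at 1e-9 precision."""
    cols = _SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df[cols].to_csv(path, index=False, float_format="%.9f", encoding="utf-8")


def read_trials(path, kind: str = "reproduction") -> pd.DataFrame:
    """Read and validate a trial-table CSV written by :func:`write_trials`."""
    df = pd.read_csv(path, encoding="utf-8")
    cols = _SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        raise SchemaError(f"unexpected columns: {extra}")
    for c in _FLOAT_COLUMNS[kind]:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()].tolist()
            raise SchemaError(f"non-numeric values in column {c!r}, rows {bad[:5]}")
    if "trial_index" in cols:
        dup = df.duplicated(subset=["subject_id", "trial_index"])
        if dup.any():
            raise SchemaError(
                f"duplicated (subject_id, trial_index) at rows {df.index[dup].tolist()[:5]}"
            )
    if kind == "reproduction":
        df["hit"] = df["hit"].astype(bool)
    return df[cols]
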