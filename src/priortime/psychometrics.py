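"""Temporal-categorization psychophysics: QUEST, psychometric fits, WF.

A two-interval forced-choice (2IFC) task measures sensory resolution of time:
a reference interval fixed at 0.9 s is compared with a probe interval placed
by a Bayesian adaptive staircase (QUEST).  The per-subject psychometric
function P(probe judged longer | probe) is fitted as a cumulative Gaussian by
maximum likelihood; the point of subjective equality (PSE) is its mean, the
75% just-noticeable difference (JND) is sigma * Phi^-1(0.75), and the Weber
fraction WF = JND / PSE is the trait-like resolution index consumed by the
mixed-model analyses.

Goodness of fit uses a deviance pseudo-R^2 against a coin-flip null responder
(deviance 2 n ln 2), with chance-level cutoffs calibrated by refitting
simulated random responders.  Split-half (odd/even trials) reliability of WF
is summarized with the Spearman-Brown correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "QuestState",
    "PsychometricFit",
    "ReliabilityResult",
    "p_choose_interval2",
    "quest_init",
    "quest_update",
    "fit_psychometric",
    "wf_from_fit",
    "bootstrap_ci",
    "pseudo_r2",
    "null_pseudo_r2_distribution",
    "above_chance",
    "split_half_reliability",
]

PHI_INV_75 = float(stats.norm.ppf(0.75))

STIM_LO = 0.5
STIM_HI = 1.3
REFERENCE_S = 0.9

# QUEST defaults: 201-point PSE grid on the stimulus range, Gaussian prior
# centered on the reference, assumed psychometric slope ~0.15 WF at 0.9 s.
QUEST_GRID_N = 201
QUEST_PRIOR_SD = 0.2
QUEST_SIGMA_ASSUMED = 0.135
QUEST_LAPSE = 0.02

FIT_LAPSE = 0.01
SIGMA_LO = 1e-4
SIGMA_HI = 1.0


def p_choose_interval2(
    i1: float | np.ndarray, i2: float | np.ndarray, wm: float
) -> float | np.ndarray:
    """Probability a scalar-variability observer judges interval 2 longer.

    Both intervals are measured with independent Gaussian noise of SD
    ``wm * interval``; the observer reports whichever measurement is larger,
    giving Phi((i2 - i1) / sqrt(wm^2 (i1^2 + i2^2))).
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if np.any(i1 <= 0) or np.any(i2 <= 0):
        raise ValueError("intervals must be > 0")
    out = stats.norm.cdf((i2 - i1) / np.sqrt(wm**2 * (i1**2 + i2**2)))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# QUEST adaptive staircase
# ---------------------------------------------------------------------------


@dataclass
class QuestState:
    """Posterior over candidate PSE values and the next probe placement.

    Probes are placed at the posterior-mean PSE offset alternately by
    +/- Phi^-1(0.75) * sigma_assumed (the 75%/25% "sweat points"): placing
    every trial exactly at the PSE would concentrate responses at p = 0.5,
    leaving the psychometric slope — hence the Weber fraction — barely
    identifiable from staircase trials.
    """

    grid: np.ndarray
    log_posterior: np.ndarray
    sigma_assumed: float = QUEST_SIGMA_ASSUMED
    lapse: float = QUEST_LAPSE
    next_stimulus_s: float = REFERENCE_S
    n_updates: int = 0
    at_bound: bool = False

    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_posterior - self.log_posterior.max())
        return p / p.sum()

    def pse_mean(self) -> float:
        return float(np.dot(self.posterior(), self.grid))


def quest_init(
    grid_n: int = QUEST_GRID_N,
    prior_mean: float = REFERENCE_S,
    prior_sd: float = QUEST_PRIOR_SD,
    sigma_assumed: float = QUEST_SIGMA_ASSUMED,
    lapse: float = QUEST_LAPSE,
) -> QuestState:
    grid = np.linspace(STIM_LO, STIM_HI, grid_n)
    log_post = stats.norm.logpdf(grid, prior_mean, prior_sd)
    state = QuestState(
        grid=grid,
        log_posterior=log_post,
        sigma_assumed=sigma_assumed,
        lapse=lapse,
    )
    state.next_stimulus_s = _placement(state)
    return state


def _placement(state: QuestState) -> float:
    sign = 1.0 if state.n_updates % 2 == 0 else -1.0
    target = state.pse_mean() + sign * PHI_INV_75 * state.sigma_assumed
    return float(np.clip(target, STIM_LO, STIM_HI))


def quest_update(state: QuestState, stimulus: float, response: bool) -> QuestState:
    """Bayesian update after observing one response at ``stimulus``.

    ``response`` is True when the probe (interval 2) was judged longer.  The
    likelihood is a cumulative Gaussian in the probe value with the assumed
    slope and lapse; the next probe is placed at the posterior-mean PSE,
    clamped to the stimulus range.
    """
    lam = state.lapse
    p_long = lam / 2 + (1 - lam) * stats.norm.cdf(
        (stimulus - state.grid) / state.sigma_assumed
    )
    like = p_long if response else 1.0 - p_long
    log_post = state.log_posterior + np.log(np.maximum(like, 1e-300))
    log_post -= log_post.max()
    new = QuestState(
        grid=state.grid,
        log_posterior=log_post,
        sigma_assumed=state.sigma_assumed,
        lapse=state.lapse,
        n_updates=state.n_updates + 1,
    )
    new.next_stimulus_s = _placement(new)
    post = new.posterior()
    # flag a posterior collapsed onto a grid boundary
    new.at_bound = bool(post[0] > 0.5 or post[-1] > 0.5)
    return new


# ---------------------------------------------------------------------------
# Psychometric MLE
# ---------------------------------------------------------------------------


@dataclass
class PsychometricFit:
    """Fitted cumulative Gaussian with derived JND/WF and fit diagnostics."""

    pse_s: float
    sigma_s: float
    jnd_s: float
    wf: float
    deviance: float
    pseudo_r2: float
    n_trials: int
    lapse: float = FIT_LAPSE
    sigma_at_bound: bool = False
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _as_xy(trials) -> tuple[np.ndarray, np.ndarray]:
    """Extract probe values and binary responses from a trial table or arrays."""
    if isinstance(trials, pd.DataFrame):
        x = trials["interval2_s"].to_numpy(dtype=float)
        r = trials["response"].to_numpy()
        if r.dtype.kind in "OUS":
            y = (r == "interval2_longer").astype(float)
        else:
            y = r.astype(float)
    else:
        x, y = trials
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    return x, y


def _nll(params: np.ndarray, x: np.ndarray, y: np.ndarray, lapse: float) -> float:
    pse, sigma = params
    p = lapse / 2 + (1 - lapse) * stats.norm.cdf((x - pse) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


# fixed multi-start schedule: (pse, sigma) initial guesses
_STARTS = [(0.9, 0.1), (0.8, 0.05), (1.0, 0.25)]


def fit_psychometric(trials, lapse: float = FIT_LAPSE) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of 2IFC responses.

    The response model is ``P(probe longer | x) = lapse/2 +
    (1 - lapse) * Phi((x - PSE) / sigma)`` with the lapse rate fixed.
    Optimization is L-BFGS-B from a fixed schedule of starting points; the
    best converged solution wins, so refits are deterministic.
    """
    x, y = _as_xy(trials)
    if len(x) < 20:
        raise ValueError(f"need >= 20 trials, got {len(x)}")
    if y.min() == y.max():
        raise ValueError("both response categories must be present")

    best = None
    bounds = [(0.2, 1.6), (SIGMA_LO, SIGMA_HI)]
    for start in _STARTS:
        res = optimize.minimize(
            _nll, start, args=(x, y, lapse), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    pse, sigma = best.x
    sigma_at_bound = sigma <= SIGMA_LO * (1 + 1e-6)
    deviance = 2.0 * best.fun  # saturated model has log-likelihood 0
    n = len(x)
    fit = PsychometricFit(
        pse_s=float(pse),
        sigma_s=float(sigma),
        jnd_s=float(sigma * PHI_INV_75),
        wf=float(sigma * PHI_INV_75 / pse),
        deviance=float(deviance),
        pseudo_r2=1.0 - deviance / (2.0 * n * np.log(2.0)),
        n_trials=n,
        lapse=lapse,
        sigma_at_bound=bool(sigma_at_bound),
    )
    return fit


def wf_from_fit(fit: PsychometricFit) -> tuple[float, float]:
    """(JND, WF) from a fitted curve: JND = sigma * Phi^-1(0.75), WF = JND/PSE."""
    if fit.pse_s <= 0:
        raise ValueError("PSE must be > 0 to form a Weber fraction")
    jnd = fit.sigma_s * PHI_INV_75
    return jnd, jnd / fit.pse_s


def bootstrap_ci(
    trials, B: int = 1000, seed: int = 0, lapse: float = FIT_LAPSE
) -> dict[str, tuple[float, float]]:
    """Nonparametric percentile bootstrap (2.5/97.5) for PSE, sigma, WF."""
    if B < 100:
        raise ValueError("B must be >= 100")
    x, y = _as_xy(trials)
    rng = np.random.default_rng(seed)
    n = len(x)
    draws = {"pse_s": [], "sigma_s": [], "wf": []}
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            f = fit_psychometric((x[idx], y[idx]), lapse=lapse)
        except ValueError:
            failures += 1
            continue
        draws["pse_s"].append(f.pse_s)
        draws["sigma_s"].append(f.sigma_s)
        draws["wf"].append(f.wf)
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in draws.items()
    }


def pseudo_r2(fit: PsychometricFit, n_trials: int | None = None) -> float:
    """1 - deviance / (2 n ln 2): fraction of coin-flip deviance explained."""
    n = fit.n_trials if n_trials is None else n_trials
    return 1.0 - fit.deviance / (2.0 * n * np.log(2.0))


def null_pseudo_r2_distribution(
    stimuli: np.ndarray,
    iters: int = 10_000,
    seed: int = 0,
    lapse: float = FIT_LAPSE,
) -> dict:
    """Chance-level pseudo-R^2 percentiles from simulated random responders.

    Responses at the given stimuli are fair coin flips; each simulated
    session is refitted and its pseudo-R^2 collected.  Returns the 95th,
    99th and 99.9th empirical percentiles plus the raw values; sessions whose
    refit fails (single response category) are dropped and counted.
    """
    if iters < 1000:
        raise ValueError("iters must be >= 1000")
    stimuli = np.asarray(stimuli, dtype=float)
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(iters):
        y = (rng.random(len(stimuli)) < 0.5).astype(float)
        try:
            f = fit_psychometric((stimuli, y), lapse=lapse)
        except ValueError:
            failures += 1
            continue
        values.append(f.pseudo_r2)
    values = np.asarray(values)
    return {
        "p95": float(np.percentile(values, 95)),
        "p99": float(np.percentile(values, 99)),
        "p999": float(np.percentile(values, 99.9)),
        "n_failures": failures,
        "values": values,
    }


def above_chance(observed_pseudo_r2: float, null_table: dict, percentile: str = "p95") -> bool:
    """Classify a subject's fit as better than random responding."""
    return observed_pseudo_r2 > null_table[percentile]


@dataclass(frozen=True)
class ReliabilityResult:
    rho: float
    rho_sb: float
    n_subjects: int


def split_half_reliability(per_subject_trials: dict) -> ReliabilityResult:
    """Odd-even split-half reliability of WF across subjects.

    WF is fitted separately on odd- and even-indexed trials of each subject;
    the Spearman correlation of the two half estimates is corrected to
    full-length reliability with the Spearman-Brown formula 2 rho / (1 + rho).
    Subjects whose half-fits fail are dropped with a warning.
    """
    import warnings

    odd_wf, even_wf = [], []
    for sid, trials in per_subject_trials.items():
        x, y = _as_xy(trials)
        if len(x) < 40:
            warnings.warn(f"subject {sid}: fewer than 20 trials per half; dropped")
            continue
        try:
            f_odd = fit_psychometric((x[1::2], y[1::2]))
            f_even = fit_psychometric((x[0::2], y[0::2]))
        except ValueError as err:
            warnings.warn(f"subject {sid}: half-fit failed ({err}); dropped")
            continue
        odd_wf.append(f_odd.wf)
        even_wf.append(f_even.wf)
    if len(odd_wf) < 5:
        raise ValueError("need at least 5 subjects with successful half-fits")
    if np.allclose(odd_wf, even_wf):
        rho = 1.0
    else:
        rho = float(stats.spearmanr(odd_wf, even_wf).statistic)
    return ReliabilityResult(rho=rho, rho_sb=2 * rho / (1 + rho), n_subjects=len(odd_wf))
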