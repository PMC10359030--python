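"""Per-subject trial censoring before regression analyses.

Three screens, applied in a fixed order to one subject's reproduction
trials, with the error defined as ``production_s - sample_s``:

1. gross errors: |error| > 3 s (essentially impossible under central
   tendency, which keeps typical errors well under 0.2 s);
2. extreme errors: |error| more than 4 SDs from the subject's mean
   whole-session error, computed after stage 1;
3. influential trials: Cook's distance above 1 in a per-subject simple
   linear regression of production on sample, re-screened iteratively until
   no trial exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["CensoringConfig", "CensoringReport", "censor_trials", "cooks_distances"]


@dataclass(frozen=True)
class CensoringConfig:
    abs_error_s: float = 3.0
    sd_threshold: float = 4.0
    cooks_threshold: float = 1.0
    max_cooks_passes: int = 10
    min_trials: int = 10


@dataclass
class CensoringReport:
    n_input: int
    n_removed_stage1: int = 0
    n_removed_stage2: int = 0
    n_removed_stage3: int = 0
    removed_trial_ids: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_removed_stage1 + self.n_removed_stage2 + self.n_removed_stage3

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_stage1": self.n_removed_stage1,
            "n_removed_stage2": self.n_removed_stage2,
            "n_removed_stage3": self.n_removed_stage3,
            "fraction_removed": self.fraction_removed,
            "removed_trial_ids": list(self.removed_trial_ids),
        }


def cooks_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distances for a simple linear regression of y on x."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return res.get_influence().cooks_distance[0]


def censor_trials(
    trials: pd.DataFrame, config: CensoringConfig | None = None
) -> tuple[pd.DataFrame, CensoringReport]:
    """Apply the three screening stages to one subject's trials.

    Returns the surviving trials (original row order preserved) and a report
    with per-stage removal counts and the removed trial indices.  Raises if
    fewer than ``min_trials`` trials survive.
    """
    config = config or CensoringConfig()
    if trials["subject_id"].nunique() > 1:
        raise ValueError("censor_trials operates on a single subject")
    df = trials.sort_values("trial_index")
    report = CensoringReport(n_input=len(df))
    error = df["production_s"] - df["sample_s"]

    # stage 1: gross absolute errors
    keep1 = error.abs() <= config.abs_error_s
    report.n_removed_stage1 = int((~keep1).sum())
    report.removed_trial_ids += df.loc[~keep1, "trial_index"].tolist()
    df = df[keep1]
    error = error[keep1]

    # stage 2: errors beyond N SDs of the subject's mean overall error
    mu, sd = error.mean(), error.std(ddof=1)
    if sd > 0:
        keep2 = (error - mu).abs() <= config.sd_threshold * sd
    else:
        keep2 = pd.Series(True, index=df.index)
    report.n_removed_stage2 = int((~keep2).sum())
    report.removed_trial_ids += df.loc[~keep2, "trial_index"].tolist()
    df = df[keep2]

    # stage 3: iterative Cook's-distance screen on tp ~ ts
    for _ in range(config.max_cooks_passes):
        if len(df) < 3:
            break
        d = cooks_distances(df["sample_s"].to_numpy(), df["production_s"].to_numpy())
        bad = d > config.cooks_threshold
        if not bad.any():
            break
        report.n_removed_stage3 += int(bad.sum())
        report.removed_trial_ids += df.loc[bad, "trial_index"].tolist()
        df = df[~bad]

    if len(df) < config.min_trials:
        raise ValueError(
            f"only {len(df)} trials survive censoring (need >= {config.min_trials})"
        )
    return trials.loc[trials.index.intersection(df.index)], report
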