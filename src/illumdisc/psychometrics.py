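"""Threshold extraction: aggregate, bin, fit, invert, exclude, summarize.

Trials from the three staircases of one chromatic direction are pooled,
ordered by achieved ΔE and grouped into bins of 10; a cumulative Weibull

    p(ΔE) = γ + (1 − γ − λ)(1 − exp(−(ΔE/α)^β)),   γ = 0.5 fixed,

is fitted to the binned proportions by binomial maximum likelihood with
the lapse rate λ constrained to [0, 0.05], and the discrimination
threshold is the ΔE at 70.71% correct — the 1-up–2-down equilibrium
point. Thresholds outside (1, 50) mark the fit invalid; observers with
any invalid block × direction fit are excluded from group summaries.

The fitting surface follows the estimator/results split familiar from
statsmodels: :class:`PsychometricModel` holds the data,
``fit()`` returns a :class:`PsychometricResults` carrying parameters,
the derived threshold, a validity flag and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "BinnedData",
    "PsychometricModel",
    "PsychometricResults",
    "bin_trials",
    "fit_weibull",
    "threshold_at",
    "invert_weibull",
    "aggregate_observer",
    "bonferroni_alpha",
    "weibull_p",
]

GUESS = 0.5
LAPSE_MAX = 0.05
CRITERION = 0.7071
VALID_RANGE = (1.0, 50.0)


@dataclass(frozen=True)
class BinnedData:
    """Binned psychometric data: per-bin mean ΔE, trial count, correct count."""

    mean_de: np.ndarray
    n_trials: np.ndarray
    n_correct: np.ndarray

    def __post_init__(self):
        for name in ("mean_de", "n_trials", "n_correct"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.mean_de) == len(self.n_trials) == len(self.n_correct)):
            raise ValueError("bin arrays must be congruent")

    @property
    def proportion_correct(self) -> np.ndarray:
        return self.n_correct / self.n_trials

    def __len__(self) -> int:
        return len(self.mean_de)


def bin_trials(records, bin_size: int = 10) -> BinnedData:
    """Pool one direction's trials, sort by achieved ΔE, bin by ``bin_size``.

    The sort is stable (chronology breaks ΔE ties); the last bin absorbs
    the remainder when the trial count is not divisible by ``bin_size``.
    """
    if len(records) == 0:
        raise ValueError("no trials to bin")
    de = np.array([r.achieved_de for r in records])
    correct = np.array([r.correct for r in records], dtype=float)
    order = np.argsort(de, kind="stable")
    de, correct = de[order], correct[order]
    edges = list(range(0, len(de), bin_size))
    mean_de, n, k = [], [], []
    for i, start in enumerate(edges):
        stop = len(de) if i == len(edges) - 1 else start + bin_size
        if stop - start < bin_size and len(edges) > 1 and i == len(edges) - 1:
            pass  # remainder bin
        sl = slice(start, stop)
        mean_de.append(de[sl].mean())
        n.append(stop - start)
        k.append(correct[sl].sum())
    return BinnedData(np.array(mean_de), np.array(n), np.array(k))


def weibull_p(de, alpha: float, beta: float, lapse: float) -> np.ndarray:
    """The psychometric function value at ΔE = de."""
    de = np.asarray(de, dtype=float)
    return GUESS + (1.0 - GUESS - lapse) * (1.0 - np.exp(-((de / alpha) ** beta)))


def invert_weibull(
    alpha: float, beta: float, lapse: float, criterion: float = CRITERION
) -> float:
    """Closed-form ΔE at which the Weibull reaches the criterion."""
    if not (GUESS < criterion < 1.0 - lapse):
        raise ValueError(
            f"criterion {criterion} outside attainable range "
            f"({GUESS}, {1.0 - lapse})"
        )
    return float(
        alpha * (-np.log(1.0 - (criterion - GUESS) / (GUESS - lapse))) ** (1.0 / beta)
    )


class PsychometricModel:
    """Binomial MLE of the cumulative-Weibull psychometric function.

    Built from :class:`BinnedData` (or a trial-record list, which is
    binned with the default bin size). Guess rate fixed at 0.5; lapse
    bounded to [0, 0.05]; α, β optimized on the log scale with
    multi-start (log-spaced α grid over the data range, β ∈ {1, 2, 4},
    λ ∈ {0, 0.025}) because staircase-concentrated data yields
    multimodal likelihoods.
    """

    def __init__(self, data):
        if not isinstance(data, BinnedData):
            data = bin_trials(list(data))
        if len(data) < 2:
            raise ValueError("need at least 2 bins to fit")
        self.data = data

    def loglike(self, alpha: float, beta: float, lapse: float) -> float:
        p = np.clip(
            weibull_p(self.data.mean_de, alpha, beta, lapse), 1e-9, 1.0 - 1e-9
        )
        k, n = self.data.n_correct, self.data.n_trials
        return float(np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))

    def _neg_ll(self, theta):
        la, lb, lapse = theta
        return -self.loglike(np.exp(la), np.exp(lb), lapse)

    def fit(self, n_alpha_starts: int = 4) -> "PsychometricResults":
        de = self.data.mean_de
        lo = max(float(de[de > 0].min()) if (de > 0).any() else 0.5, 0.5)
        hi = max(float(de.max()), lo * 2)
        alpha_grid = np.geomspace(lo, hi, n_alpha_starts)
        bounds = [(np.log(1e-2), np.log(1e4)), (np.log(0.05), np.log(20.0)),
                  (0.0, LAPSE_MAX)]
        best = None
        for a0 in alpha_grid:
            for b0 in (1.0, 2.0, 4.0):
                for l0 in (0.0, 0.025):
                    res = minimize(
                        self._neg_ll,
                        x0=np.array([np.log(a0), np.log(b0), l0]),
                        method="L-BFGS-B",
                        bounds=bounds,
                    )
                    if best is None or res.fun < best.fun:
                        best = res
        la, lb, lapse = best.x
        return PsychometricResults(
            model=self,
            alpha=float(np.exp(la)),
            beta=float(np.exp(lb)),
            lapse=float(np.clip(lapse, 0.0, LAPSE_MAX)),
            loglike=-float(best.fun),
        )


@dataclass(frozen=True)
class PsychometricResults:
    """Fitted Weibull parameters and the derived discrimination threshold."""

    model: PsychometricModel
    alpha: float
    beta: float
    lapse: float
    loglike: float
    guess: float = GUESS

    @property
    def threshold_7071(self) -> float:
        return invert_weibull(self.alpha, self.beta, self.lapse, CRITERION)

    @property
    def valid(self) -> bool:
        t = self.threshold_7071
        return bool(VALID_RANGE[0] < t < VALID_RANGE[1]) and np.isfinite(t)

    def predict(self, de) -> np.ndarray:
        return weibull_p(de, self.alpha, self.beta, self.lapse)

    def threshold(self, criterion: float = CRITERION) -> float:
        return invert_weibull(self.alpha, self.beta, self.lapse, criterion)

    def summary(self) -> str:
        d = self.model.data
        lines = [
            "Cumulative-Weibull psychometric fit (binomial MLE)",
            "=" * 50,
            f"bins: {len(d)}   trials: {int(d.n_trials.sum())}   "
            f"log-likelihood: {self.loglike:.3f}",
            f"alpha (81.6% scale): {self.alpha:10.4f}",
            f"beta  (slope):       {self.beta:10.4f}",
            f"lapse rate:          {self.lapse:10.4f}   (bounds [0, {LAPSE_MAX}])",
            f"guess rate:          {self.guess:10.4f}   (fixed)",
            f"threshold @ 70.71%:  {self.threshold_7071:10.4f} dE",
            f"valid (threshold in (1, 50)): {self.valid}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Binned proportions with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        ax.scatter(d.mean_de, d.proportion_correct, s=4 * d.n_trials, alpha=0.7)
        grid = np.linspace(0, max(d.mean_de.max() * 1.1, 1.0), 200)
        ax.plot(grid, self.predict(grid))
        ax.axhline(CRITERION, ls=":", lw=0.8)
        ax.set_xlabel("illumination change (CIELUV dE)")
        ax.set_ylabel("proportion correct")
        ax.set_ylim(0.4, 1.02)
        return ax


def fit_weibull(binned: BinnedData) -> PsychometricResults:
    """Convenience wrapper: fit the Weibull model to binned data."""
    return PsychometricModel(binned).fit()


def threshold_at(fit: PsychometricResults, criterion: float = CRITERION) -> float:
    """ΔE at the criterion percent correct, from a fitted model."""
    return invert_weibull(fit.alpha, fit.beta, fit.lapse, criterion)


def aggregate_observer(threshold_table: pd.DataFrame) -> tuple:
    """Average block thresholds per observer × direction; summarize group.

    Input columns: observer, block, direction, threshold, valid. An
    observer with any invalid fit in any block × direction is flagged
    excluded (the fit rows are kept so the exclusion is auditable).
    Returns ``(per_observer, group_summary)``: per-direction means per
    observer (with an ``excluded`` flag), and mean ± SEM across the
    non-excluded observers.
    """
    required = {"observer", "block", "direction", "threshold", "valid"}
    missing = required - set(threshold_table.columns)
    if missing:
        raise ValueError(f"threshold table missing columns: {sorted(missing)}")
    excluded = (
        threshold_table.groupby("observer")["valid"].apply(lambda v: not v.all())
    )
    per_obs = (
        threshold_table.groupby(["observer", "direction"], as_index=False)["threshold"]
        .mean()
    )
    per_obs["excluded"] = per_obs["observer"].map(excluded)
    kept = per_obs[~per_obs["excluded"]]
    if kept.empty:
        raise ValueError("all observers excluded; no group summary possible")
    group = (
        kept.groupby("direction")["threshold"]
        .agg(
            mean="mean",
            sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    return per_obs, group


def bonferroni_alpha(n_comparisons: int, family_alpha: float = 0.05) -> float:
    """Bonferroni-adjusted per-comparison significance level."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return family_alpha / n_comparisons
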