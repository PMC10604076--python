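"""Swarm-sensing statistics.

Each well yields tens of particle-droplets, every one an independent
measurement of the same sample.  This module implements the statistical
layer built on that multiplicity: a decision threshold set at
mu + k*sigma of the negative-control intensity distribution (k = 3 by
default), the fraction of particles above that threshold, the standard
error of the mean as a function of particles measured, one-tailed Welch
t tests, positive/negative sample classification, Monte Carlo
subsampling of particle counts, a comparison of the fraction-above
versus mean-intensity readout statistics, and a dose-response / limit of
detection summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ThresholdModel:
    """Negative-control threshold mu0 + k * sigma0 (sample SD, n-1)."""

    mu0: float
    sigma0: float
    k: float = 3.0

    @property
    def threshold(self) -> float:
        return self.mu0 + self.k * self.sigma0


@dataclass(frozen=True)
class ClassificationRule:
    """Positive iff at least ``min_count`` particles exceed the threshold,
    or, when ``min_fraction`` is set, iff the fraction above reaches it."""

    min_count: int = 1
    min_fraction: float | None = None


@dataclass
class SwarmSummary:
    condition: float | str
    n_particles: int
    mean_intensity: float
    sem: float
    fraction_above: float
    classification: str


@dataclass(frozen=True)
class MonteCarloConfig:
    n_values: tuple[int, ...] = tuple(range(1, 51))
    reps: int = 5000
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if any(n < 1 for n in self.n_values):
            raise ValueError("all subset sizes must be >= 1")


def compute_threshold(negative_intensities, k: float = 3.0) -> ThresholdModel:
    """Fit the mu + k*sigma threshold to a negative-control population."""
    x = np.asarray(negative_intensities, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 negative-control intensities")
    return ThresholdModel(mu0=float(x.mean()), sigma0=float(x.std(ddof=1)), k=k)


def fraction_above(intensities, model: ThresholdModel) -> float:
    """Fraction of intensities strictly above the model threshold."""
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty intensity list")
    return float(np.count_nonzero(x > model.threshold) / x.size)


def sem_curve(intensities, n_values) -> pd.DataFrame:
    """Standard error of the mean versus particles measured.

    SEM(n) = s / sqrt(n) with s the full-population sample SD; the
    relative SEM s / (mean * sqrt(n)) is reported alongside.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("population SD needs n >= 2")
    s = x.std(ddof=1)
    mean = x.mean()
    n = np.asarray(list(n_values), dtype=int)
    sem = s / np.sqrt(n)
    rel = sem / mean if mean != 0 else np.full_like(sem, np.nan)
    return pd.DataFrame({"n": n, "sem": sem, "relative_sem": rel})


def one_tailed_t_test(sample_a, sample_b) -> float:
    """One-tailed Welch test of mean(b) > mean(a); returns the p-value.

    Identical samples give p = 0.5 (t = 0), including the degenerate
    zero-variance equal-mean case; swapping the arguments maps p to 1-p.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.5
        return 0.0 if b.mean() > a.mean() else 1.0
    res = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
    return float(res.pvalue)


def classify_sample(intensities, model: ThresholdModel,
                    rule: ClassificationRule = ClassificationRule()) -> str:
    """'positive' or 'negative' by counting particles above the threshold."""
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty intensity list")
    if rule.min_fraction is not None:
        positive = fraction_above(x, model) >= rule.min_fraction
    else:
        positive = int(np.count_nonzero(x > model.threshold)) >= rule.min_count
    return "positive" if positive else "negative"


def summarize(intensities, model: ThresholdModel, condition,
              rule: ClassificationRule = ClassificationRule()) -> SwarmSummary:
    x = np.asarray(intensities, dtype=float).ravel()
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return SwarmSummary(
        condition=condition,
        n_particles=int(x.size),
        mean_intensity=float(x.mean()),
        sem=sem,
        fraction_above=fraction_above(x, model),
        classification=classify_sample(x, model, rule),
    )


# ---------------------------------------------------------------------------
# Monte Carlo subsampling


def _subsets(rng: np.random.Generator, population: np.ndarray, n: int,
             reps: int, with_replacement: bool) -> np.ndarray:
    """(reps, n) matrix of subsampled intensities."""
    size = population.size
    if with_replacement:
        idx = rng.integers(0, size, size=(reps, n))
    else:
        if n > size:
            raise ValueError(f"subset size {n} exceeds population size {size}")
        idx = np.argsort(rng.random((reps, size)), axis=1)[:, :n]
    return population[idx]


def monte_carlo_subsample(neg_intensities, pos_intensities, model: ThresholdModel,
                          config: MonteCarloConfig = MonteCarloConfig(),
                          rule: ClassificationRule = ClassificationRule(),
                          ) -> pd.DataFrame:
    """Monte Carlo study of readout robustness versus particles measured.

    For every subset size n and repeat, n intensities are drawn
    uniformly without replacement from the positive population (with a
    matched draw from the negative population for the t test), and three
    metrics are computed: mean intensity, one-tailed Welch p-value
    (positive above negative) and fraction above threshold.  The
    false-negative rate is the fraction of repeats whose positive subset
    classifies negative under ``rule``.

    Returns a tidy frame with one row per n: columns
    ``n, mean_mean_intensity, sd_mean_intensity, mean_p_value,
    sd_p_value, mean_fraction_above, sd_fraction_above,
    false_negative_rate``.  The p-value columns are NaN at n < 2, where
    a two-sample t test is undefined.  Deterministic per
    ``config.seed``; per-n substreams make the result independent of the
    order of ``n_values``.
    """
    neg = np.asarray(neg_intensities, dtype=float).ravel()
    pos = np.asarray(pos_intensities, dtype=float).ravel()
    thr = model.threshold
    rows = []
    for n in config.n_values:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(n)]))
        pos_draw = _subsets(rng, pos, n, config.reps, config.with_replacement)
        neg_draw = _subsets(rng, neg, n, config.reps, config.with_replacement)

        means = pos_draw.mean(axis=1)
        above = (pos_draw > thr).sum(axis=1)
        fracs = above / n
        if rule.min_fraction is not None:
            negative_call = fracs < rule.min_fraction
        else:
            negative_call = above < rule.min_count

        if n >= 2:
            pvals = np.array(
                [one_tailed_t_test(neg_draw[r], pos_draw[r]) for r in range(config.reps)]
            )
            p_mean, p_sd = float(pvals.mean()), float(pvals.std(ddof=0))
        else:
            p_mean = p_sd = float("nan")

        rows.append(
            {
                "n": int(n),
                "mean_mean_intensity": float(means.mean()),
                "sd_mean_intensity": float(means.std(ddof=0)),
                "mean_p_value": p_mean,
                "sd_p_value": p_sd,
                "mean_fraction_above": float(fracs.mean()),
                "sd_fraction_above": float(fracs.std(ddof=0)),
                "false_negative_rate": float(negative_call.mean()),
            }
        )
    return pd.DataFrame(rows)


def compare_methods(neg_repeats, pos_repeats, k: float = 3.0) -> tuple[float, float]:
    """Compare the fraction-above and mean-intensity readout statistics.

    Each element of ``neg_repeats`` / ``pos_repeats`` is one
    experimental repeat's per-particle intensity population.  Per
    repeat, the threshold is fit to that repeat's own negative control,
    so a background shift shared within a repeat cancels in the
    fraction-above statistic but not in the raw mean.  Returns
    (p_fraction, p_mean), each a one-tailed Welch p-value for the
    positive arm exceeding the negative arm.
    """
    if len(neg_repeats) < 2 or len(pos_repeats) < 2:
        raise ValueError("need >= 2 repeats per condition")
    if len(neg_repeats) != len(pos_repeats):
        raise ValueError("repeats must be paired (same count per arm)")
    f_neg, f_pos, m_neg, m_pos = [], [], [], []
    for neg, pos in zip(neg_repeats, pos_repeats):
        model = compute_threshold(neg, k=k)
        f_neg.append(fraction_above(neg, model))
        f_pos.append(fraction_above(pos, model))
        m_neg.append(float(np.mean(neg)))
        m_pos.append(float(np.mean(pos)))
    return one_tailed_t_test(f_neg, f_pos), one_tailed_t_test(m_neg, m_pos)


# ---------------------------------------------------------------------------
# dose response


@dataclass
class DoseResponseFit:
    slope: float
    intercept: float
    r_squared: float
    fit_range: tuple[float, float]
    lod_estimate: float | None  # None = not detected at any tested dose
    concentrations: np.ndarray
    mean_intensities: np.ndarray


def fit_dose_response(table: pd.DataFrame, threshold_model: ThresholdModel | None = None,
                      fit_range: tuple[float, float] | None = None,
                      k: float = 3.0) -> DoseResponseFit:
    """Dose-response line and operational limit of detection.

    ``table`` is an intensity table with numeric ``condition``
    (concentration, ng/mL) and per-particle ``mean_intensity``.  An OLS
    line is fit to the per-concentration mean intensities over
    ``fit_range`` (default: all doses).  The LOD is the lowest tested
    non-zero dose whose mean intensity exceeds the negative-control
    mu + k*sigma threshold (fit from the zero-dose particles when no
    model is supplied); ``lod_estimate`` is None when no dose exceeds
    it.
    """
    conc = pd.to_numeric(table["condition"])
    groups = table.assign(condition=conc).groupby("condition")["mean_intensity"]
    means = groups.mean()
    if means.size < 3:
        raise ValueError("need >= 3 concentrations")
    c = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)

    if threshold_model is None:
        if 0.0 not in means.index:
            raise ValueError("no zero-dose group and no threshold model supplied")
        threshold_model = compute_threshold(
            table.loc[conc == 0.0, "mean_intensity"], k=k
        )

    if fit_range is None:
        fit_range = (float(c.min()), float(c.max()))
    in_range = (c >= fit_range[0]) & (c <= fit_range[1])
    res = stats.linregress(c[in_range], y[in_range])

    exceed = c[(c > 0) & (y > threshold_model.threshold)]
    lod = float(exceed.min()) if exceed.size else None
    return DoseResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        fit_range=fit_range,
        lod_estimate=lod,
        concentrations=c,
        mean_intensities=y,
    )
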