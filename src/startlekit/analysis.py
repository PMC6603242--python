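"""Inhibition statistics, distribution fits and threshold estimation.

The central quantity is the full-combinatorial ratio set: every pairwise
ratio ``A_pre[i] / A_base[j]`` between pre-stimulus-trial startle
amplitudes and baseline (no-pre-stimulus) amplitudes.  The inhibition
statistic (PPI, or GPIAS for a gap pre-stimulus) is one minus the median
of that set; its standard error comes from bootstrapping the two
amplitude samples.  Startle amplitudes are well described as log-normal,
so the log-ratios are approximately Gaussian — which is what makes the
median of ratios a natural, outlier-robust effect measure.

The PPI as a function of pre-stimulus level follows a hard-sigmoid
(zero below the sensory threshold, linear rise, saturation); the fitted
breakpoint estimates the hearing threshold at that frequency.

Two presentation layers coexist:

* spec-level functions (:func:`full_combinatorial_ratios`,
  :func:`bootstrap_se`, :func:`fit_hard_sigmoid`, ...) — the primitive
  surface;
* model objects (:class:`InhibitionModel`, :class:`HardSigmoidModel`,
  :class:`LogNormalModel`) whose ``fit()`` returns a results object with
  estimates, uncertainties and a ``summary()`` table, in the style of
  statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RatioSet",
    "InhibitionResult",
    "LogNormalFit",
    "HardSigmoidFit",
    "full_combinatorial_ratios",
    "inhibition_statistic",
    "bootstrap_se",
    "fit_lognormal",
    "lognormality_check",
    "fit_hard_sigmoid",
    "hard_sigmoid",
    "compare_groups",
    "InhibitionModel",
    "InhibitionResults",
    "LogNormalModel",
    "LogNormalResults",
    "HardSigmoidModel",
    "HardSigmoidResults",
]

DEFAULT_N_BOOTSTRAP = 100_000


# ---------------------------------------------------------------------------
# ratio statistics

@dataclass
class RatioSet:
    """All pairwise pre/baseline amplitude ratios."""

    ratios: np.ndarray
    n_pre: int
    n_base: int

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if len(self.ratios) != self.n_pre * self.n_base:
            raise ValueError("ratio count must equal n_pre * n_base")
        if np.any(self.ratios <= 0):
            raise ValueError("ratios must be strictly positive")

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class InhibitionResult:
    """Inhibition statistic (1 - median ratio) with bootstrap SE."""

    statistic: float
    se: float
    n_bootstrap: int

    def __post_init__(self) -> None:
        if self.statistic > 1:
            raise ValueError("inhibition statistic cannot exceed 1")
        if self.se < 0:
            raise ValueError("se must be nonnegative")


def _check_amplitudes(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError(f"{name} must be nonempty")
    if np.any(a <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return a


def full_combinatorial_ratios(a_pre, a_base) -> RatioSet:
    """Every pairwise ratio ``a_pre[i] / a_base[j]``, row-major order."""
    a_pre = _check_amplitudes(a_pre, "a_pre")
    a_base = _check_amplitudes(a_base, "a_base")
    return RatioSet(np.ravel(a_pre[:, None] / a_base[None, :]),
                    len(a_pre), len(a_base))


def inhibition_statistic(r: RatioSet) -> float:
    """1 - median(ratios); the median of an even count is the midpoint of
    the central pair."""
    return 1.0 - float(np.median(r.ratios))


def _bootstrap_medians(a_pre, a_base, n_bootstrap, rng, chunk=2000) -> np.ndarray:
    """Medians of the full-combinatorial ratio set for resampled groups."""
    n_p, n_b = len(a_pre), len(a_base)
    out = np.empty(n_bootstrap)
    done = 0
    while done < n_bootstrap:
        b = min(chunk, n_bootstrap - done)
        pre = a_pre[rng.integers(0, n_p, size=(b, n_p))]
        base = a_base[rng.integers(0, n_b, size=(b, n_b))]
        ratios = pre[:, :, None] / base[:, None, :]
        out[done:done + b] = np.median(ratios.reshape(b, -1), axis=1)
        done += b
    return out


def bootstrap_se(
    a_pre,
    a_base,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    seed: int = 0,
) -> InhibitionResult:
    """Bootstrap standard error of the inhibition statistic.

    Both amplitude groups are independently resampled with replacement
    (preserving the two-sample structure) and the full-combinatorial
    median recomputed per replicate; the SE is the standard deviation of
    the replicate medians.
    """
    a_pre = _check_amplitudes(a_pre, "a_pre")
    a_base = _check_amplitudes(a_base, "a_base")
    if len(a_pre) < 2 or len(a_base) < 2:
        raise ValueError("bootstrap requires >= 2 trials in each group")
    rng = np.random.Generator(np.random.PCG64(seed))
    medians = _bootstrap_medians(a_pre, a_base, n_bootstrap, rng)
    stat = inhibition_statistic(full_combinatorial_ratios(a_pre, a_base))
    return InhibitionResult(stat, float(np.std(medians)), n_bootstrap)


# ---------------------------------------------------------------------------
# distribution fits

@dataclass(frozen=True)
class LogNormalFit:
    """Maximum-likelihood log-normal parameters of a positive sample."""

    mu: float
    sigma: float
    loglik: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def fit_lognormal(a) -> LogNormalFit:
    """Closed-form MLE: mu = mean(ln A), sigma = sqrt(mean((ln A - mu)^2))."""
    a = _check_amplitudes(a, "amplitudes")
    if a.size < 2:
        raise ValueError("need at least two observations")
    la = np.log(a)
    mu = float(np.mean(la))
    sigma = float(np.sqrt(np.mean((la - mu) ** 2)))
    if sigma == 0:
        raise ValueError("zero variance sample; log-normal fit is degenerate")
    loglik = float(np.sum(stats.lognorm.logpdf(a, s=sigma, scale=np.exp(mu))))
    return LogNormalFit(mu, sigma, loglik)


@dataclass(frozen=True)
class NormalityReport:
    """Descriptive normality check of log-ratios."""

    statistic: float
    pvalue: float
    qq_max_deviation: float
    n: int


def lognormality_check(ratios) -> NormalityReport:
    """D'Agostino-Pearson normality test of ln(ratios), plus the maximum
    absolute deviation of the QQ plot from its fitted line.

    Descriptive only: a small p-value flags departure from the log-normal
    picture, but no decision is attached.
    """
    ratios = _check_amplitudes(ratios, "ratios")
    if ratios.size < 8:
        raise ValueError("normality check requires n >= 8")
    lr = np.log(ratios)
    k2, p = stats.normaltest(lr)
    (osm, osr), (slope, intercept, _) = stats.probplot(lr, dist="norm")
    # deviation in units of the fitted scale, so it is scale-free
    qq_dev = float(np.max(np.abs(osr - (slope * osm + intercept))) / slope)
    return NormalityReport(float(k2), float(p), qq_dev, ratios.size)


# ---------------------------------------------------------------------------
# hard-sigmoid threshold fit

def hard_sigmoid(x, threshold: float, slope: float, saturation: float):
    """clip(slope * (x - threshold), 0, saturation).

    Exactly zero below the threshold (the lower asymptote is fixed at
    zero: below the sensory threshold the pre-stimulus is inaudible and
    cannot inhibit the startle), rising linearly, saturating at
    ``saturation``.
    """
    return np.clip(slope * (np.asarray(x, dtype=float) - threshold), 0.0, saturation)


@dataclass(frozen=True)
class HardSigmoidFit:
    """Fitted hard-sigmoid stimulus-response function.

    ``threshold_dbspl`` is the level where the function first departs from
    zero — the estimated sensory threshold.  ``no_response`` flags data
    with no detectable inhibition at any level, where a threshold is
    undefined.
    """

    threshold_dbspl: float
    slope: float
    saturation: float
    rss: float
    no_response: bool = False

    def __call__(self, x):
        return hard_sigmoid(x, self.threshold_dbspl, self.slope, self.saturation)


def _hs_residuals(params, x, y, w):
    th, m, s = params
    return (hard_sigmoid(x, th, m, s) - y) * w


def fit_hard_sigmoid(levels_dbspl, ppi_values, weights=None) -> HardSigmoidFit:
    """Least-squares hard-sigmoid fit with a multi-start threshold grid.

    The threshold grid spans the level range at 0.1 dB resolution; each
    start is refined continuously (trust-region least squares with
    ``slope > 0`` and ``0 < saturation <= 1``).  ``weights``, when given,
    are used as inverse-variance weights (pass ``1/se**2``).
    """
    x = np.asarray(levels_dbspl, dtype=float)
    y = np.asarray(ppi_values, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct levels")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.sqrt(np.asarray(weights, dtype=float))
    if np.all(y <= 0):
        # no inhibition anywhere: flat zero fits best, threshold undefined
        rss = float(np.sum((y * w) ** 2))
        return HardSigmoidFit(float(x.max()), 0.0, 1e-12, rss, no_response=True)

    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    s0 = float(np.clip(np.max(y), 1e-3, 1.0))
    best = None
    # coarse grid of starts, each refined continuously
    for th0 in np.arange(lo - 0.5 * span, hi, max(span / 12.0, 0.1)):
        rising = x > th0
        if rising.sum() >= 2:
            m0 = max(float(np.polyfit(x[rising], y[rising], 1)[0]), 1e-4)
        else:
            m0 = max(s0 / max(span, 1.0), 1e-4)
        res = optimize.least_squares(
            _hs_residuals, [th0, m0, s0],
            bounds=([lo - 2 * span, 1e-9, 1e-9], [hi + span, np.inf, 1.0]),
            args=(x, y, w), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    # fine local grid around the winner for the piecewise-flat directions
    th_c = best.x[0]
    for th0 in np.arange(th_c - 1.0, th_c + 1.0 + 1e-9, 0.1):
        res = optimize.least_squares(
            _hs_residuals, [th0, best.x[1], best.x[2]],
            bounds=([lo - 2 * span, 1e-9, 1e-9], [hi + span, np.inf, 1.0]),
            args=(x, y, w), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if res.cost < best.cost - 1e-15:
            best = res
    th, m, s = best.x
    rss = float(2 * best.cost)
    return HardSigmoidFit(float(th), float(m), float(s), rss)


# ---------------------------------------------------------------------------
# group comparison

EXACT_CUTOVER_N = 12


def compare_groups(stats_a, stats_b) -> float:
    """Two-sided Mann-Whitney U rank-sum test between per-animal statistics.

    Exact permutation null (enumeration of all group assignments) when the
    combined sample is small (<= 12); otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    if len(a) + len(b) <= EXACT_CUTOVER_N:
        return _exact_rank_sum(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumerating all C(n_a+n_b, n_a) assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    n = len(pooled)
    mean_u = n_a * (n - n_a) / 2.0
    obs = abs(_u_statistic(a, b) - mean_u)
    count = 0
    total = 0
    idx = np.arange(n)
    for comb in combinations(idx, n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mean_u) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# model-object layer

def _summary_table(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * max(len(title), 30)]
    lines += [f"{k:<{width}}{v}" for k, v in rows]
    return "\n".join(lines)


class InhibitionModel:
    """Inhibition (PPI/GPIAS) of startle amplitudes by a pre-stimulus.

    Built from two positive amplitude samples: pre-stimulus trials and
    baseline trials.  ``fit()`` computes the full-combinatorial median
    ratio statistic and its bootstrap standard error.
    """

    def __init__(self, a_pre, a_base, label: str = "inhibition"):
        self.a_pre = _check_amplitudes(a_pre, "a_pre")
        self.a_base = _check_amplitudes(a_base, "a_base")
        self.label = label

    @classmethod
    def from_dataframe(cls, df, kind_pre: str = "gap", kind_base: str = "nogap",
                       amplitude_col: str = "amplitude", kind_col: str = "kind"):
        """Build from a per-trial table with kind and amplitude columns."""
        pre = df.loc[df[kind_col] == kind_pre, amplitude_col].to_numpy()
        base = df.loc[df[kind_col] == kind_base, amplitude_col].to_numpy()
        return cls(pre, base, label=f"{kind_pre} vs {kind_base}")

    def fit(self, n_bootstrap: int = DEFAULT_N_BOOTSTRAP, seed: int = 0
            ) -> "InhibitionResults":
        res = bootstrap_se(self.a_pre, self.a_base, n_bootstrap, seed)
        ratios = full_combinatorial_ratios(self.a_pre, self.a_base)
        return InhibitionResults(self, res, ratios)


@dataclass
class InhibitionResults:
    model: InhibitionModel
    result: InhibitionResult
    ratios: RatioSet

    @property
    def statistic(self) -> float:
        return self.result.statistic

    @property
    def se(self) -> float:
        return self.result.se

    def conf_int(self, n_se: float = 1.96) -> tuple[float, float]:
        return (self.statistic - n_se * self.se, self.statistic + n_se * self.se)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return _summary_table(
            f"Inhibition results ({self.model.label})",
            [
                ("n pre / n base", f"{self.ratios.n_pre} / {self.ratios.n_base}"),
                ("ratios (full comb.)", f"{len(self.ratios)}"),
                ("statistic (1 - median)", f"{self.statistic:.4f}"),
                ("bootstrap SE", f"{self.se:.4f}"),
                ("bootstrap replicates", f"{self.result.n_bootstrap}"),
                ("95% CI", f"[{lo:.4f}, {hi:.4f}]"),
            ],
        )

    def plot_ratio_histogram(self, ax=None, bins=30):
        """Histogram of ratios with the fitted log-normal overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fit = fit_lognormal(self.ratios.ratios)
        ax.hist(self.ratios.ratios, bins=bins, density=True, alpha=0.6)
        grid = np.linspace(self.ratios.ratios.min(), self.ratios.ratios.max(), 400)
        ax.plot(grid, stats.lognorm.pdf(grid, s=fit.sigma, scale=np.exp(fit.mu)))
        ax.set_xlabel("amplitude ratio (pre / baseline)")
        ax.set_ylabel("density")
        return ax


class LogNormalModel:
    """Log-normal model of startle amplitudes (or amplitude ratios)."""

    def __init__(self, a):
        self.a = _check_amplitudes(a, "amplitudes")

    def fit(self) -> "LogNormalResults":
        return LogNormalResults(self, fit_lognormal(self.a))


@dataclass
class LogNormalResults:
    model: LogNormalModel
    fit_: LogNormalFit

    @property
    def mu(self) -> float:
        return self.fit_.mu

    @property
    def sigma(self) -> float:
        return self.fit_.sigma

    def se(self) -> tuple[float, float]:
        """Asymptotic SEs of (mu, sigma): sigma/sqrt(n), sigma/sqrt(2n)."""
        n = self.model.a.size
        return self.sigma / math.sqrt(n), self.sigma / math.sqrt(2 * n)

    def summary(self) -> str:
        se_mu, se_sigma = self.se()
        return _summary_table(
            "Log-normal MLE",
            [
                ("n", f"{self.model.a.size}"),
                ("mu (log-location)", f"{self.mu:.4f} (SE {se_mu:.4f})"),
                ("sigma (log-scale)", f"{self.sigma:.4f} (SE {se_sigma:.4f})"),
                ("log-likelihood", f"{self.fit_.loglik:.2f}"),
            ],
        )


class HardSigmoidModel:
    """Hard-sigmoid stimulus-response model for threshold audiometry.

    Built from PPI values measured at several pre-stimulus levels; the
    fitted breakpoint estimates the hearing threshold at the probe
    frequency.
    """

    def __init__(self, levels_dbspl, ppi_values, ppi_se=None):
        self.levels = np.asarray(levels_dbspl, dtype=float)
        self.ppi = np.asarray(ppi_values, dtype=float)
        self.ppi_se = None if ppi_se is None else np.asarray(ppi_se, dtype=float)

    @classmethod
    def from_dataframe(cls, df, level_col="level_dbspl", ppi_col="ppi",
                       se_col="se"):
        se = df[se_col].to_numpy() if se_col in df else None
        return cls(df[level_col].to_numpy(), df[ppi_col].to_numpy(), se)

    def fit(self) -> "HardSigmoidResults":
        weights = None
        if self.ppi_se is not None and np.all(self.ppi_se > 0):
            weights = 1.0 / self.ppi_se**2
        return HardSigmoidResults(self, fit_hard_sigmoid(self.levels, self.ppi, weights))


@dataclass
class HardSigmoidResults:
    model: HardSigmoidModel
    fit_: HardSigmoidFit

    @property
    def threshold_dbspl(self) -> float:
        return self.fit_.threshold_dbspl

    def predict(self, levels=None):
        x = self.model.levels if levels is None else levels
        return self.fit_(x)

    def summary(self) -> str:
        rows = [
            ("n levels", f"{len(self.model.levels)}"),
            ("threshold (dB SPL)", "undefined (no response)" if self.fit_.no_response
             else f"{self.threshold_dbspl:.2f}"),
            ("slope (PPI / dB)", f"{self.fit_.slope:.4f}"),
            ("saturation", f"{self.fit_.saturation:.4f}"),
            ("residual SS", f"{self.fit_.rss:.6g}"),
        ]
        return _summary_table("Hard-sigmoid threshold fit", rows)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.levels, self.model.ppi
        if self.model.ppi_se is not None:
            ax.errorbar(x, y, yerr=self.model.ppi_se, fmt="o")
        else:
            ax.plot(x, y, "o")
        grid = np.linspace(x.min() - 2, x.max() + 2, 400)
        ax.plot(grid, self.fit_(grid), "-")
        if not self.fit_.no_response:
            ax.axvline(self.threshold_dbspl, ls="--", alpha=0.5)
        ax.set_xlabel("pre-stimulus level (dB SPL)")
        ax.set_ylabel("PPI")
        return ax
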