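"""Nonparametric cross-over analysis: descriptives, Friedman test, post-hoc
pairwise comparisons with Bonferroni-Holm correction, and a synthetic
repeated-measures dataset generator.

The analysis mirrors a five-treatment cross-over experiment
(IPPV_first, CCSV_A, CCSV_B, CCSV_C, IPPV_last; n subjects, complete matrix):

* descriptives are the median, quartiles (linear interpolation between order
  statistics), minimum and maximum;
* the omnibus comparison is the Friedman test on within-subject mid-ranks with
  the standard tie correction, with a p-value from the chi-squared
  approximation or from the permutation null (exhaustive enumeration of the
  per-subject rank permutations when feasible, Monte-Carlo otherwise);
* single comparisons are exact two-sided Wilcoxon signed-rank tests per
  treatment pair (sign-flip null distribution, mid-ranks for tied absolute
  differences), Holm-adjusted; a Conover rank-based alternative is available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TREATMENTS",
    "CrossoverDataset",
    "Descriptives",
    "FriedmanResult",
    "PairwiseResult",
    "TableReport",
    "descriptives",
    "friedman_test",
    "posthoc_pairwise",
    "wilcoxon_exact",
    "holm_adjust",
    "simulate_crossover_dataset",
    "estimate_power",
    "analyze_table",
    "REFERENCE_VARIABLES",
]

TREATMENTS = ("IPPV_first", "CCSV_A", "CCSV_B", "CCSV_C", "IPPV_last")


@dataclass
class CrossoverDataset:
    """Complete subjects × treatments matrix of one measured variable."""

    values: np.ndarray  # (n_subjects, k)
    treatments: tuple[str, ...] = TREATMENTS
    variable: str = "value"
    units: str = ""
    subjects: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects × treatments matrix")
        n, k = self.values.shape
        if k != len(self.treatments):
            raise ValueError("number of columns must match treatments")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix must be complete (no missing cells)")
        if self.subjects is None:
            self.subjects = [f"S{i + 1:02d}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.values.shape[1]

    def column(self, treatment: str) -> np.ndarray:
        return self.values[:, self.treatments.index(treatment)]

    @classmethod
    def from_long(
        cls,
        frame: pd.DataFrame,
        variable: str | None = None,
        subject_col: str = "subject",
        treatment_col: str = "treatment",
        value_col: str = "value",
        variable_col: str = "variable",
        units: str = "",
        treatments: Sequence[str] | None = None,
    ) -> "CrossoverDataset":
        """Build from a long table with subject/treatment/value columns.

        ``variable`` filters a stacked multi-variable table on
        ``variable_col``.  Column names are remappable so spreadsheet exports
        with different headers can be ingested.
        """
        df = frame
        if variable is not None and variable_col in df.columns:
            df = df[df[variable_col] == variable]
            if df.empty:
                raise ValueError(f"variable {variable!r} not present in table")
        wide = df.pivot(index=subject_col, columns=treatment_col, values=value_col)
        if wide.isna().any().any():
            raise ValueError("matrix must be complete (no missing cells)")
        cols = list(treatments) if treatments is not None else [
            t for t in TREATMENTS if t in wide.columns
        ] or list(wide.columns)
        wide = wide[cols]
        return cls(
            values=wide.to_numpy(),
            treatments=tuple(cols),
            variable=variable or "value",
            units=units,
            subjects=[str(s) for s in wide.index],
        )

    def to_long(self) -> pd.DataFrame:
        rows = [
            {
                "subject": s,
                "treatment": t,
                "variable": self.variable,
                "value": self.values[i, j],
            }
            for i, s in enumerate(self.subjects)
            for j, t in enumerate(self.treatments)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Descriptives:
    """Nonparametric summary of one sample."""

    median: float
    q25: float
    q75: float
    min: float
    max: float


def descriptives(values: Sequence[float]) -> Descriptives:
    """Median, quartiles (linear interpolation), minimum and maximum."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("descriptives of an empty sample are undefined")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return Descriptives(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        min=float(x.min()),
        max=float(x.max()),
    )


@dataclass(frozen=True)
class PairwiseResult:
    """One post-hoc treatment comparison."""

    pair: tuple[str, str]
    p_raw: float
    p_adjusted: Optional[float] = None
    statistic: Optional[float] = None
    degenerate: bool = False  # all paired differences zero


@dataclass
class FriedmanResult:
    """Omnibus Friedman test plus (optionally) Holm-adjusted pairwise tests."""

    statistic: float
    df: int
    p_omnibus: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    p_method: str = "chi2"
    n_resamples: Optional[int] = None


def _friedman_core(values: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Tie-corrected Friedman statistic, its S numerator, and the mid-ranks."""
    n, k = values.shape
    ranks = sps.rankdata(values, axis=1)
    colsums = ranks.sum(axis=0)
    s_num = float(((colsums - n * (k + 1) / 2.0) ** 2).sum())
    denom = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    stat = 0.0 if denom == 0 else (k - 1) * s_num / denom
    return stat, s_num, ranks


def _s_statistic(colsums: np.ndarray, n: int, k: int) -> np.ndarray:
    return ((colsums - n * (k + 1) / 2.0) ** 2).sum(axis=-1)


def friedman_test(
    data: CrossoverDataset | np.ndarray,
    p_method: str = "chi2",
    n_resamples: int = 10000,
    max_exact: int = 100000,
    seed: int | None = None,
) -> FriedmanResult:
    """Friedman omnibus test on within-subject mid-ranks.

    ``p_method="chi2"`` uses the chi-squared approximation with k−1 degrees of
    freedom.  ``p_method="permutation"`` uses the permutation null obtained by
    rearranging each subject's values across treatments: exhaustive over all
    (k!)^n arrangements when that count is at most ``max_exact``, otherwise
    Monte-Carlo with ``n_resamples`` draws and the add-one p estimate.
    """
    values = data.values if isinstance(data, CrossoverDataset) else np.asarray(data, float)
    if values.ndim != 2:
        raise ValueError("data must be a 2-D subjects × treatments matrix")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 treatments")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix must be complete (no missing cells)")

    stat, s_obs, ranks = _friedman_core(values)
    df = k - 1
    if p_method == "chi2":
        p = 1.0 if stat == 0 else float(sps.chi2.sf(stat, df))
        return FriedmanResult(stat, df, min(p, 1.0), p_method="chi2")
    if p_method != "permutation":
        raise ValueError("p_method must be 'chi2' or 'permutation'")

    # S = sum_j (R_j - n(k+1)/2)^2 is a monotone surrogate for the statistic:
    # the tie-correction denominator is invariant under within-row permutation.
    tol = 1e-9
    n_arrangements = math.factorial(k) ** n
    if n_arrangements <= max_exact:
        perms = list(itertools.permutations(range(k)))
        row_perms = np.stack(
            [ranks[:, p] for p in perms], axis=1
        )  # (n, k!, k)
        count = 0
        total = 0
        for combo in itertools.product(range(len(perms)), repeat=n):
            colsums = sum(row_perms[i, c] for i, c in enumerate(combo))
            if _s_statistic(colsums, n, k) >= s_obs - tol:
                count += 1
            total += 1
        p = count / total
        return FriedmanResult(stat, df, p, p_method="permutation", n_resamples=total)

    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_resamples, n, k)), axis=2)
    permuted = np.take_along_axis(
        np.broadcast_to(ranks, (n_resamples, n, k)), idx, axis=2
    )
    s_perm = _s_statistic(permuted.sum(axis=1), n, k)
    p = (1 + int((s_perm >= s_obs - tol).sum())) / (1 + n_resamples)
    return FriedmanResult(stat, df, p, p_method="permutation", n_resamples=n_resamples)


def wilcoxon_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, bool]:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    The null distribution of W+ (sum of ranks of positive differences) is
    computed exactly over all 2^m sign assignments by dynamic programming
    (mid-ranks are half-integers, so doubled ranks are integers), and the
    two-sided p is twice the smaller tail, capped at 1.

    Returns ``(W+, p, degenerate)`` where ``degenerate`` flags an all-zero
    difference vector (p = 1 by convention).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 0.0, 1.0, True
    ranks = sps.rankdata(np.abs(d))
    doubled = np.rint(2 * ranks).astype(int)
    w_plus2 = int(doubled[d > 0].sum())
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for s in doubled:
        nxt = dist.copy()
        nxt[s:] += dist[: total + 1 - s]
        dist = nxt
    dist /= 2.0**m
    p_ge = float(dist[w_plus2:].sum())
    p_le = float(dist[: w_plus2 + 1].sum())
    p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_plus2 / 2.0, p, False


def _conover_pairwise(values: np.ndarray, treatments: Sequence[str]):
    """Conover's post-hoc comparisons on the Friedman rank sums."""
    n, k = values.shape
    ranks = sps.rankdata(values, axis=1)
    colsums = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    b = float((colsums**2).sum()) / n
    dfree = (n - 1) * (k - 1)
    scale = 2.0 * n * (a - b) / dfree
    results = []
    for i, j in itertools.combinations(range(k), 2):
        if scale <= 0:  # all arrangements identical
            results.append(
                PairwiseResult((treatments[i], treatments[j]), 1.0, degenerate=True)
            )
            continue
        t = abs(colsums[i] - colsums[j]) / math.sqrt(scale)
        p = 2.0 * float(sps.t.sf(t, dfree))
        results.append(
            PairwiseResult((treatments[i], treatments[j]), min(p, 1.0), statistic=t)
        )
    return results


def posthoc_pairwise(
    data: CrossoverDataset | np.ndarray,
    method: str = "wilcoxon",
) -> list[PairwiseResult]:
    """Raw two-sided p-values for all treatment pairs (no correction applied)."""
    if isinstance(data, CrossoverDataset):
        values, treatments = data.values, data.treatments
    else:
        values = np.asarray(data, dtype=float)
        treatments = tuple(f"T{j + 1}" for j in range(values.shape[1]))
    if method == "conover":
        return _conover_pairwise(values, treatments)
    if method != "wilcoxon":
        raise ValueError("method must be 'wilcoxon' or 'conover'")
    results = []
    for i, j in itertools.combinations(range(values.shape[1]), 2):
        w, p, degenerate = wilcoxon_exact(values[:, i], values[:, j])
        results.append(
            PairwiseResult(
                (treatments[i], treatments[j]), p, statistic=w, degenerate=degenerate
            )
        )
    return results


def holm_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in input order.

    Sorted ascending, the i-th smallest p is multiplied by (m−i+1); running
    maxima enforce monotonicity and values are capped at 1.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def simulate_crossover_dataset(
    locations: Mapping[str, float] | Sequence[float],
    spreads: Mapping[str, float] | Sequence[float] | float = 0.0,
    n_subjects: int = 12,
    subject_sd: float = 0.0,
    distribution: str = "normal",
    seed: int | None = None,
    variable: str = "value",
    units: str = "",
    treatments: Sequence[str] | None = None,
) -> CrossoverDataset:
    """Generate a complete synthetic subjects × treatments matrix.

    Additive model: ``value(s, t) = location_t + subject_effect_s + noise``
    with ``subject_effect ~ N(0, subject_sd)`` and
    ``noise ~ N(0, spread_t)``.  With ``distribution="lognormal"`` the model is
    multiplicative, ``value = location_t * exp(subject_effect + noise)`` (the
    effects are log-scale standard deviations), which keeps the column median
    at ``location_t`` while producing the right-skew typical of variables such
    as PaO2.
    """
    if isinstance(locations, Mapping):
        if treatments is None:
            treatments = tuple(locations)
        locs = np.array([locations[t] for t in treatments], dtype=float)
    else:
        locs = np.asarray(locations, dtype=float)
        if treatments is None:
            treatments = TREATMENTS[: locs.size] if locs.size <= len(TREATMENTS) else tuple(
                f"T{j + 1}" for j in range(locs.size)
            )
    k = locs.size
    if isinstance(spreads, Mapping):
        scale = np.array([spreads[t] for t in treatments], dtype=float)
    else:
        scale = np.broadcast_to(np.asarray(spreads, dtype=float), (k,)).copy()
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    if np.any(scale < 0) or subject_sd < 0:
        raise ValueError("spreads must be non-negative")

    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, subject_sd, size=(n_subjects, 1))
    eps = rng.normal(0.0, 1.0, size=(n_subjects, k)) * scale
    if distribution == "normal":
        values = locs + b + eps
    elif distribution == "lognormal":
        values = locs * np.exp(b + eps)
    else:
        raise ValueError("distribution must be 'normal' or 'lognormal'")
    return CrossoverDataset(
        values=values,
        treatments=tuple(treatments),
        variable=variable,
        units=units,
    )


#: Default generator presets per physiological variable: per-treatment
#: location (median level), noise spread, subject effect and distribution,
#: at magnitudes typical of a 12-animal swine CPR cross-over experiment.
#: Spreads are on the log scale for lognormal variables.
REFERENCE_VARIABLES: dict[str, dict] = {
    "PaO2": dict(
        locations=dict(zip(TREATMENTS, (19.6, 48.9, 54.0, 46.0, 22.7))),
        spreads=0.5, subject_sd=0.3, distribution="lognormal", units="kPa",
    ),
    "PaCO2": dict(
        locations=dict(zip(TREATMENTS, (6.5, 6.2, 6.1, 7.8, 7.7))),
        spreads=0.25, subject_sd=0.15, distribution="lognormal", units="kPa",
    ),
    "pH_arterial": dict(
        locations=dict(zip(TREATMENTS, (7.39, 7.27, 7.33, 7.25, 7.23))),
        spreads=0.08, subject_sd=0.05, distribution="normal", units="",
    ),
    "pH_venous": dict(
        locations=dict(zip(TREATMENTS, (7.32, 7.24, 7.26, 7.26, 7.19))),
        spreads=0.05, subject_sd=0.03, distribution="normal", units="",
    ),
    "PvO2": dict(
        locations=dict(zip(TREATMENTS, (3.5, 3.3, 3.3, 3.0, 3.3))),
        spreads=0.4, subject_sd=0.2, distribution="normal", units="kPa",
    ),
    "PvCO2": dict(
        locations=dict(zip(TREATMENTS, (8.0, 8.6, 8.4, 8.4, 9.2))),
        spreads=1.0, subject_sd=0.6, distribution="normal", units="kPa",
    ),
    "SvO2": dict(
        locations=dict(zip(TREATMENTS, (39.5, 34.5, 34.5, 32.0, 28.5))),
        spreads=6.0, subject_sd=4.0, distribution="normal", units="%",
    ),
    "MAP": dict(
        locations=dict(zip(TREATMENTS, (42.5, 40.1, 39.2, 37.0, 22.4))),
        spreads=7.0, subject_sd=5.0, distribution="normal", units="mmHg",
    ),
    "MAP_CVP": dict(
        locations=dict(zip(TREATMENTS, (24.0, 23.7, 26.5, 25.4, 19.9))),
        spreads=2.5, subject_sd=1.5, distribution="normal", units="mmHg",
    ),
}


def estimate_power(
    locations: Mapping[str, float] | Sequence[float],
    spreads: Mapping[str, float] | Sequence[float] | float,
    n_subjects: int = 12,
    subject_sd: float = 0.0,
    alpha: float = 0.05,
    n_sims: int = 500,
    distribution: str = "normal",
    seed: int | None = None,
) -> float:
    """Simulation-based power of the Friedman omnibus test.

    Fraction of ``n_sims`` synthetic datasets (drawn from the generator with
    the given effect pattern) whose chi-squared omnibus p-value is at most
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        ds = simulate_crossover_dataset(
            locations,
            spreads,
            n_subjects=n_subjects,
            subject_sd=subject_sd,
            distribution=distribution,
            seed=int(rng.integers(2**31 - 1)),
        )
        if friedman_test(ds).p_omnibus <= alpha:
            hits += 1
    return hits / n_sims


@dataclass
class TableReport:
    """Descriptive + inferential report for one variable."""

    dataset: CrossoverDataset
    descriptives: dict[str, Descriptives]
    friedman: FriedmanResult

    def pairwise_matrix(self) -> pd.DataFrame:
        """Holm-adjusted pairwise p-values in upper-triangle table layout."""
        treatments = self.dataset.treatments
        mat = pd.DataFrame(
            np.nan, index=treatments[:-1], columns=treatments[1:], dtype=float
        )
        for res in self.friedman.pairwise:
            a, b = res.pair
            mat.loc[a, b] = res.p_adjusted
        return mat

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.dataset.treatments:
            d = self.descriptives[t]
            rows.append(
                {
                    "treatment": t,
                    "median": d.median,
                    "q25": d.q25,
                    "q75": d.q75,
                    "min": d.min,
                    "max": d.max,
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        unit = f" [{self.dataset.units}]" if self.dataset.units else ""
        lines = [
            f"Variable: {self.dataset.variable}{unit} "
            f"(n = {self.dataset.n_subjects})",
            "",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3g}"),
            "",
            f"Friedman chi2 = {self.friedman.statistic:.3f}, "
            f"df = {self.friedman.df}, p = {self.friedman.p_omnibus:.4g} "
            f"({self.friedman.p_method})",
            "",
            "Holm-adjusted pairwise p-values:",
            self.pairwise_matrix().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def analyze_table(
    dataset: CrossoverDataset,
    posthoc: str = "wilcoxon",
    p_method: str = "chi2",
    seed: int | None = None,
) -> TableReport:
    """Full pipeline for one variable: descriptives, omnibus, Holm post-hoc."""
    desc = {t: descriptives(dataset.column(t)) for t in dataset.treatments}
    omnibus = friedman_test(dataset, p_method=p_method, seed=seed)
    raw = posthoc_pairwise(dataset, method=posthoc)
    adjusted = holm_adjust([r.p_raw for r in raw])
    omnibus.pairwise = [
        PairwiseResult(
            r.pair, r.p_raw, float(a), statistic=r.statistic, degenerate=r.degenerate
        )
        for r, a in zip(raw, adjusted)
    ]
    return TableReport(dataset=dataset, descriptives=desc, friedman=omnibus)
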