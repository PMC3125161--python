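"""Score statistics: extreme-value fits, P-values, posteriors, thresholds,
error curves and length-dependence regressions.

All operations consume labelled score samples: records of
(pair_id, L1, L2, score, label ∈ {same, diff}, context ∈ {gapless, fold,
homology}), read and written as TSV with a mandatory header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SAMPLE_COLUMNS = ["pair_id", "L1", "L2", "score", "label", "context"]
CONTEXTS = ("gapless", "fold", "homology")
LABELS = ("same", "diff")

#: evaluation grid for curves (scores live in [0, 1])
GRID_STEP = 0.001
#: histogram bin width for posterior densities
POSTERIOR_BIN = 0.01
#: histogram bin width for the Gumbel goodness-of-fit statistic
GUMBEL_FIT_BIN = 0.005
#: a 0.5-upcrossing must persist for this many grid points to count
STABLE_CROSSING_K = 5


def default_grid(lo: float = 0.0, hi: float = 1.0, step: float = GRID_STEP) -> np.ndarray:
    return np.round(np.arange(lo, hi + step / 2, step), 9)


def read_score_sample(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if not np.all(np.isfinite(df["score"].to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite scores")
    return df


def write_score_sample(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SAMPLE_COLUMNS, float_format="%.6f")


# ---------------------------------------------------------------------------
# extreme value (Gumbel) fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GumbelParams:
    location: float
    scale: float
    fit_r2: float
    method: str = "mle"


def fit_gumbel(scores, min_n: int = 100) -> GumbelParams:
    """Maximum-likelihood fit of a right-skewed Gumbel distribution.

    ``fit_r2`` is the coefficient of determination of expected vs observed
    bin frequencies (bin width 0.005).
    """
    x = np.asarray(scores, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} scores, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) score sample")
    loc, scale = stats.gumbel_r.fit(x)

    lo = np.floor(x.min() / GUMBEL_FIT_BIN) * GUMBEL_FIT_BIN
    hi = np.ceil(x.max() / GUMBEL_FIT_BIN) * GUMBEL_FIT_BIN
    edges = np.arange(lo, hi + GUMBEL_FIT_BIN / 2, GUMBEL_FIT_BIN)
    observed = np.histogram(x, bins=edges)[0] / x.size
    cdf = stats.gumbel_r.cdf(edges, loc=loc, scale=scale)
    expected = np.diff(cdf)
    ss_res = float(((observed - expected) ** 2).sum())
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return GumbelParams(location=float(loc), scale=float(scale), fit_r2=r2)


def gumbel_pvalue(p: GumbelParams, s: float) -> float:
    """Survival 1 − exp(−exp(−(s − μ)/β))."""
    if p.scale <= 0:
        raise ValueError("scale must be positive")
    return float(stats.gumbel_r.sf(s, loc=p.location, scale=p.scale))


# ---------------------------------------------------------------------------
# empirical P-values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PValueCurve:
    grid: np.ndarray
    values: np.ndarray
    context: str
    n: int
    _sorted_scores: np.ndarray

    def evaluate(self, s: float) -> float:
        """Exact empirical survival P(S ≥ s)."""
        idx = np.searchsorted(self._sorted_scores, s, side="left")
        return float((self.n - idx) / self.n)


def empirical_pvalue_curve(
    null_scores, context: str = "gapless", grid: np.ndarray | None = None
) -> PValueCurve:
    """Right-continuous empirical survival of a null score sample."""
    x = np.sort(np.asarray(null_scores, dtype=float))
    if x.size == 0:
        raise ValueError("null score sample is empty")
    if grid is None:
        grid = default_grid(min(0.0, np.floor(x[0])), max(1.0, np.ceil(x[-1])))
    vals = (x.size - np.searchsorted(x, grid, side="left")) / x.size
    return PValueCurve(grid=grid, values=vals, context=context, n=x.size, _sorted_scores=x)


# ---------------------------------------------------------------------------
# priors from a two-scheme classification mapping
# ---------------------------------------------------------------------------

def priors_from_mapping(mapping: dict[str, tuple[str, str]]) -> float:
    """Prior probability of class co-membership from a two-scheme mapping.

    Over all unordered domain pairs, counts pairs whose domains share the
    class in *both* schemes and pairs that differ in both; pairs agreeing in
    only one scheme are excluded.  Returns same-both / (same-both + diff-both).
    """
    if len(mapping) < 2:
        raise ValueError("need at least two domains")
    items = list(mapping.values())
    n = len(items)
    total = n * (n - 1) // 2

    def _pairs_sharing(key) -> int:
        counts: dict = {}
        for v in items:
            k = key(v)
            counts[k] = counts.get(k, 0) + 1
        return sum(c * (c - 1) // 2 for c in counts.values())

    same_both = _pairs_sharing(lambda v: v)
    same_first = _pairs_sharing(lambda v: v[0])
    same_second = _pairs_sharing(lambda v: v[1])
    diff_both = total - same_first - same_second + same_both
    denom = same_both + diff_both
    if denom == 0:
        raise ValueError("no pairs agree or disagree in both schemes; prior undefined")
    return same_both / denom


# ---------------------------------------------------------------------------
# Bayesian posterior curves and phase-transition thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorCurve:
    edges: np.ndarray  # bin edges, length B+1
    values: np.ndarray  # posterior P(same | s in bin); NaN where unpopulated
    populated: np.ndarray  # bool mask: some observation fell in the bin
    counts_same: np.ndarray
    counts_diff: np.ndarray
    prior_same: float
    context: str = "fold"

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def posterior_curve(
    same,
    diff,
    prior_same: float,
    bin_width: float = POSTERIOR_BIN,
    context: str = "fold",
) -> PosteriorCurve:
    """P(same | score) per bin via Bayes on Laplace-smoothed binned densities."""
    same = np.asarray(same, dtype=float)
    diff = np.asarray(diff, dtype=float)
    if same.size == 0 or diff.size == 0:
        raise ValueError("both samples must be nonempty")
    if not 0.0 < prior_same < 1.0:
        raise ValueError("prior must be strictly between 0 and 1")
    allx = np.concatenate([same, diff])
    lo = min(0.0, np.floor(allx.min() / bin_width) * bin_width)
    hi = max(1.0, np.ceil(allx.max() / bin_width) * bin_width)
    nb = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nb + 1)
    cs = np.histogram(same, bins=edges)[0].astype(float)
    cd = np.histogram(diff, bins=edges)[0].astype(float)
    populated = (cs + cd) > 0
    fs = (cs + 1.0) / (same.size + nb)
    fd = (cd + 1.0) / (diff.size + nb)
    post = fs * prior_same / (fs * prior_same + fd * (1.0 - prior_same))
    values = np.where(populated, post, np.nan)
    return PosteriorCurve(
        edges=edges,
        values=values,
        populated=populated,
        counts_same=cs,
        counts_diff=cd,
        prior_same=prior_same,
        context=context,
    )


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    posterior_at_threshold: float
    type_I: float  # P(S >= s* | diff): a priori false-positive rate (P-value at s*)
    type_II: float  # P(S < s* | same): a priori false-negative rate
    post_error_above: float  # P(diff | S >= s*)
    post_error_below: float  # P(same | S < s*)
    context: str = "fold"


def phase_threshold(c: PosteriorCurve, k: int = STABLE_CROSSING_K) -> ThresholdReport:
    """Smallest score at which the posterior reaches 0.5 and stays there.

    The crossing must persist over the next *k* populated bins (anti-noise
    guard).  The threshold is the left edge of the crossing bin, so the
    decision rule is "call same iff S ≥ threshold".
    """
    idx_pop = np.flatnonzero(c.populated)
    vals = c.values[idx_pop]
    cross = None
    for r, v in enumerate(vals):
        if v >= 0.5 and np.all(vals[r : r + k + 1] >= 0.5):
            cross = r
            break
    if cross is None:
        raise ValueError(
            "no stable 0.5 upcrossing in posterior curve; populated values: "
            + np.array2string(vals, precision=3, max_line_width=100)
        )
    bin_idx = int(idx_pop[cross])
    s_star = float(c.edges[bin_idx])

    n_same = c.counts_same.sum()
    n_diff = c.counts_diff.sum()
    p_ge_diff = float(c.counts_diff[bin_idx:].sum() / n_diff)  # type I
    p_lt_same = float(c.counts_same[:bin_idx].sum() / n_same)  # type II
    p_ge_same = 1.0 - p_lt_same
    pi = c.prior_same
    above = p_ge_diff * (1 - pi) + p_ge_same * pi
    below = p_lt_same * pi + (1.0 - p_ge_diff) * (1 - pi)
    post_err_above = p_ge_diff * (1 - pi) / above if above > 0 else float("nan")
    post_err_below = p_lt_same * pi / below if below > 0 else float("nan")
    return ThresholdReport(
        threshold=s_star,
        posterior_at_threshold=float(c.values[bin_idx]),
        type_I=p_ge_diff,
        type_II=p_lt_same,
        post_error_above=post_err_above,
        post_error_below=post_err_below,
        context=c.context,
    )


# ---------------------------------------------------------------------------
# error curves and ranking statistics
# ---------------------------------------------------------------------------

def error_curve(same, diff, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Type I (P(S ≥ t | diff)) and type II (P(S < t | same)) per threshold."""
    same = np.sort(np.asarray(same, dtype=float))
    diff = np.sort(np.asarray(diff, dtype=float))
    if same.size == 0 or diff.size == 0:
        raise ValueError("both samples must be nonempty")
    if grid is None:
        allx = np.concatenate([same, diff])
        grid = default_grid(min(0.0, np.floor(allx.min())), max(1.0, np.ceil(allx.max())))
    type_i = (diff.size - np.searchsorted(diff, grid, side="left")) / diff.size
    type_ii = np.searchsorted(same, grid, side="left") / same.size
    return pd.DataFrame({"threshold": grid, "type_I": type_i, "type_II": type_ii})


def top_hit_rate(df: pd.DataFrame) -> float:
    """Fraction of queries whose best-scoring partner is labelled 'same'.

    Expects columns query, partner, score, label; every query must have at
    least one same and one diff partner.  Score ties are broken by the
    smallest partner id.
    """
    for col in ("query", "partner", "score", "label"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    hits = 0
    queries = 0
    for query, grp in df.groupby("query", sort=True):
        labels = set(grp["label"])
        if not {"same", "diff"} <= labels:
            raise ValueError(f"query {query!r} lacks a same or diff partner")
        top = grp.sort_values(["score", "partner"], ascending=[False, True]).iloc[0]
        hits += int(top["label"] == "same")
        queries += 1
    return hits / queries


# ---------------------------------------------------------------------------
# length-dependence regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthRegressionReport:
    slope: float
    slope_per_1000: float
    adjusted_r2: float
    intercept: float
    weighted: bool
    which_length: str
    high_only: float | None
    n_groups: int


def length_regression(
    df: pd.DataFrame,
    which_length: str = "min",
    high_only: float | None = None,
    weighted: bool = True,
) -> LengthRegressionReport:
    """Regress per-length mean score on length, weighted by length frequency.

    Records are grouped by the chosen length (first, second or min of the two
    domain lengths); the per-length mean scores are fitted by (weighted)
    least squares with the per-length record counts as weights.  ``high_only``
    restricts to records with score above the given threshold first.
    """
    if which_length == "first":
        length = df["L1"].to_numpy(dtype=float)
    elif which_length == "second":
        length = df["L2"].to_numpy(dtype=float)
    elif which_length == "min":
        length = np.minimum(df["L1"].to_numpy(dtype=float), df["L2"].to_numpy(dtype=float))
    else:
        raise ValueError("which_length must be 'first', 'second' or 'min'")
    score = df["score"].to_numpy(dtype=float)
    if high_only is not None:
        keep = score > high_only
        length, score = length[keep], score[keep]
    grouped = pd.DataFrame({"length": length, "score": score}).groupby("length")["score"]
    means = grouped.mean()
    counts = grouped.count()
    if len(means) < 3:
        raise ValueError(f"need at least 3 distinct lengths, got {len(means)}")
    X = sm.add_constant(means.index.to_numpy(dtype=float))
    w = counts.to_numpy(dtype=float) if weighted else np.ones(len(means))
    res = sm.WLS(means.to_numpy(), X, weights=w).fit()
    slope = float(res.params[1])
    return LengthRegressionReport(
        slope=slope,
        slope_per_1000=slope * 1000.0,
        adjusted_r2=float(res.rsquared_adj),
        intercept=float(res.params[0]),
        weighted=weighted,
        which_length=which_length,
        high_only=high_only,
        n_groups=len(means),
    )


def symmetric_score(s_ab: float, s_ba: float) -> float:
    """Symmetrised score of an asymmetric scorer: the average of both orders."""
    return 0.5 * (s_ab + s_ba)
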