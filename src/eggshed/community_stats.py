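"""Phenology and community statistics for the egg-collection time series.

Covers effort normalization (tow volume), per-collection temperature,
sliding-window abundance, the above/below-mean-temperature t-test,
season-by-year ANOVA with Tukey HSD, Bray-Curtis dissimilarities with
log(x+1) transform, one-way PERMANOVA with permutation p-values, NMDS
ordination, Yates-corrected 2x2 chi-square, the Wilcoxon signed-rank
test, and monthly presence-fraction tables.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from sklearn.manifold import MDS
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io_formats import CollectionEvent

__all__ = [
    "AbundanceMatrix",
    "PresenceBin",
    "PresenceTable",
    "tow_volume",
    "collection_temperature",
    "sliding_window_mean",
    "temperature_split_test",
    "seasonal_anova",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "nmds",
    "chisq_yates",
    "wilcoxon_signed_rank",
    "monthly_presence",
    "monthly_mean_matrix",
    "season_of",
]


@dataclass
class AbundanceMatrix:
    """Collections (or month-averages) x species abundance table."""

    data: pd.DataFrame  # rows indexed by collection or period label
    transform_applied: str = "none"  # none | log1p

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.transform_applied not in ("none", "log1p"):
            raise ValueError("transform must be 'none' or 'log1p'")

    def log1p(self) -> "AbundanceMatrix":
        if self.transform_applied == "log1p":
            return self
        return AbundanceMatrix(np.log1p(self.data), "log1p")


class PresenceBin(str, enum.Enum):
    GE90 = ">=0.90"
    GE75 = ">=0.75"
    GE50 = ">=0.50"
    GE25 = ">=0.25"
    GT0 = ">0"
    ZERO = "0"
    NO_DATA = "no-data"


def presence_bin(fraction: float) -> PresenceBin:
    if np.isnan(fraction):
        return PresenceBin.NO_DATA
    if fraction >= 0.90:
        return PresenceBin.GE90
    if fraction >= 0.75:
        return PresenceBin.GE75
    if fraction >= 0.50:
        return PresenceBin.GE50
    if fraction >= 0.25:
        return PresenceBin.GE25
    if fraction > 0:
        return PresenceBin.GT0
    return PresenceBin.ZERO


@dataclass
class PresenceTable:
    """Species x month fractions of collections containing the species."""

    fractions: pd.DataFrame  # species rows, month columns, values in [0,1] or NaN
    bins: pd.DataFrame  # same shape, PresenceBin values

    def __post_init__(self) -> None:
        vals = self.fractions.values
        if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 1:
            raise ValueError("presence fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Effort and temperature
# ---------------------------------------------------------------------------

def tow_volume(pulls: int, net_diameter: float, depth: float) -> float:
    """Water volume screened by a vertical tow series, in cubic meters.

    volume = pulls * pi * (net_diameter/2)^2 * depth.  The survey's
    geometry (4 pulls, 1 m net, 5 m depth) gives ~15.7, i.e. about 16 m^3.
    """
    if pulls <= 0 or net_diameter <= 0 or depth <= 0:
        raise ValueError("pulls, net_diameter and depth must all be positive")
    return pulls * np.pi * (net_diameter / 2.0) ** 2 * depth


def collection_temperature(
    temps: pd.Series, collection_time: pd.Timestamp
) -> float:
    """Mean of the 10 nearest readings before and 10 after the collection.

    Returns NaN (with a warning) when either side has fewer than 10
    readings.
    """
    t = pd.Timestamp(collection_time)
    temps = temps.sort_index()
    before = temps[temps.index <= t]
    after = temps[temps.index > t]
    if len(before) < 10 or len(after) < 10:
        warnings.warn(
            f"fewer than 10 temperature readings on one side of {t}; "
            "temperature treated as missing"
        )
        return float("nan")
    return float((before.iloc[-10:].sum() + after.iloc[:10].sum()) / 20.0)


# ---------------------------------------------------------------------------
# Abundance series
# ---------------------------------------------------------------------------

def sliding_window_mean(
    events: Sequence[CollectionEvent],
    window_days: int = 21,
    step_days: int = 14,
) -> pd.Series:
    """Mean eggs/collection in sliding windows (3 weeks, overlapping 1 week).

    Windows start at the first collection date; each is labeled by its
    center date; windows with no collections are omitted.
    """
    if not events:
        return pd.Series(dtype=float)
    dates = pd.Series([ev.datetime for ev in events])
    totals = pd.Series([ev.total_eggs for ev in events], dtype=float)
    start = dates.min().normalize()
    end = dates.max()
    centers, means = [], []
    w0 = start
    while w0 <= end:
        w1 = w0 + pd.Timedelta(days=window_days)
        in_win = (dates >= w0) & (dates < w1)
        if in_win.any():
            centers.append(w0 + pd.Timedelta(days=window_days / 2))
            means.append(totals[in_win].mean())
        w0 = w0 + pd.Timedelta(days=step_days)
    return pd.Series(means, index=pd.DatetimeIndex(centers), name="mean_eggs_per_collection")


# ---------------------------------------------------------------------------
# Temperature split and seasonal ANOVA
# ---------------------------------------------------------------------------

def temperature_split_test(
    events: Sequence[CollectionEvent],
    exclude: set[str] = frozenset(),
    species: str | None = None,
) -> dict:
    """Pooled-variance t-test of egg totals below vs above the mean temperature.

    Collections are split at the grand mean of their temperatures;
    totals exclude the species in ``exclude`` (or, if ``species`` is
    given, count only that species).  Two-sided Student t with
    df = n1 + n2 - 2.
    """
    evs = [ev for ev in events if ev.temperature is not None and not np.isnan(ev.temperature)]
    if len(evs) < 4:
        raise ValueError("need at least 4 collections with temperature")
    temps = np.array([ev.temperature for ev in evs])
    if species is not None:
        totals = np.array([ev.counts.get(species, 0) for ev in evs], dtype=float)
    else:
        totals = np.array(
            [sum(c for sp, c in ev.counts.items() if sp not in exclude) for ev in evs],
            dtype=float,
        )
    mean_t = temps.mean()
    below = totals[temps < mean_t]
    above = totals[temps >= mean_t]
    if len(below) < 2 or len(above) < 2:
        raise ValueError("a temperature group is empty or too small")
    if below.var(ddof=1) == 0 and above.var(ddof=1) == 0 and below.mean() == above.mean():
        # identical constant groups: no evidence of a difference
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(below, above, equal_var=True)
    return {
        "t": float(t),
        "df": len(below) + len(above) - 2,
        "p": float(p),
        "mean_temperature": float(mean_t),
        "group_means": (float(below.mean()), float(above.mean())),
        "group_ns": (len(below), len(above)),
    }


_SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def season_of(when: pd.Timestamp) -> str:
    """Meteorological season of a date."""
    return _SEASONS[pd.Timestamp(when).month]


def _collection_year(when: pd.Timestamp, year_start_month: int = 9) -> int:
    t = pd.Timestamp(when)
    return t.year if t.month >= year_start_month else t.year - 1


def seasonal_anova(
    events: Sequence[CollectionEvent],
    season_map=season_of,
    year_start_month: int = 9,
) -> dict:
    """One-way ANOVA of egg totals across season-by-year groups + Tukey HSD.

    Groups are (season, collection year), the collection year starting
    in September.  Returns F, degrees of freedom, p, and the Tukey HSD
    pairwise table; a degenerate (zero-variance) layout is flagged with
    F = NaN.
    """
    if not events:
        raise ValueError("no events")
    totals = np.array([ev.total_eggs for ev in events], dtype=float)
    labels = np.array(
        [
            f"{season_map(ev.datetime)}-{_collection_year(ev.datetime, year_start_month)}"
            for ev in events
        ]
    )
    groups = [totals[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 season-year groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    n = len(totals)
    k = len(groups)
    if np.allclose(totals.var(), 0.0):
        return {
            "F": float("nan"),
            "df_between": k - 1,
            "df_within": n - k,
            "p": float("nan"),
            "degenerate": True,
            "tukey": None,
        }
    F, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(totals, labels)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {
        "F": float(F),
        "df_between": k - 1,
        "df_within": n - k,
        "p": float(p),
        "degenerate": False,
        "tukey": tukey_df,
    }


# ---------------------------------------------------------------------------
# Dissimilarities, PERMANOVA, NMDS
# ---------------------------------------------------------------------------

def bray_curtis(matrix: AbundanceMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities between rows.

    d(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk), in [0, 1]; a pair of
    all-zero rows is defined as d = 0 with a warning.
    """
    if isinstance(matrix, AbundanceMatrix):
        X = matrix.data.values.astype(float)
    elif isinstance(matrix, pd.DataFrame):
        X = matrix.values.astype(float)
    else:
        X = np.asarray(matrix, dtype=float)
    n = len(X)
    D = np.zeros((n, n))
    zero_rows = X.sum(axis=1) == 0
    for i in range(n):
        num = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        den = (X[i] + X[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    if zero_rows.sum() >= 2:
        warnings.warn("all-zero rows present; their mutual dissimilarity is set to 0")
    return D


def _ss_within(D2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def _pseudo_f(D2: np.ndarray, labels: np.ndarray, ss_total: float) -> float:
    n = len(labels)
    a = len(np.unique(labels))
    ss_w = _ss_within(D2, labels)
    ss_b = ss_total - ss_w
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def permanova(
    dissimilarity: np.ndarray,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """One-way PERMANOVA: pseudo-F from partitioned squared dissimilarities.

    SS_total = sum of squared dissimilarities / n; SS_within analogously
    per group; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).  The
    p-value counts label permutations with pseudo-F >= observed,
    p = (count + 1)/(n_perm + 1).  ``exhaustive=True`` enumerates all
    distinct label arrangements instead (exact p, no +1 correction
    needed on the identity permutation which is always included).
    """
    D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("dissimilarity matrix does not match labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 groups")
    for g in np.unique(labels):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    D2 = D**2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    f_obs = _pseudo_f(D2, labels, ss_total)
    if exhaustive:
        perms = set(itertools.permutations(labels))
        f_perm = np.array([_pseudo_f(D2, np.array(p), ss_total) for p in perms])
        p_val = float((f_perm >= f_obs - 1e-12).mean())
        return float(f_obs), p_val
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(D2, perm, ss_total) >= f_obs - 1e-12:
            count += 1
    return float(f_obs), (count + 1) / (n_perm + 1)


def pairwise_permanova(
    dissimilarity: np.ndarray,
    labels: Sequence,
    pairs: Sequence[tuple] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """PERMANOVA restricted to each pair of groups.

    Unadjusted permutation p-values by default; ``bonferroni=True``
    multiplies by the number of pairs (capped at 1).
    """
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    if pairs is None:
        pairs = list(itertools.combinations(sorted(present), 2))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        if a not in present or b not in present:
            raise ValueError(f"label {a!r} or {b!r} absent from data")
        idx = np.flatnonzero((labels == a) | (labels == b))
        sub = np.asarray(dissimilarity)[np.ix_(idx, idx)]
        f, p = permanova(sub, labels[idx], n_perm=n_perm, seed=int(rng.integers(2**31)))
        if bonferroni:
            p = min(1.0, p * len(pairs))
        rows.append({"group_a": a, "group_b": b, "pseudo_F": f, "p": p})
    return pd.DataFrame(rows)


def nmds(
    dissimilarity: np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Non-metric multidimensional scaling (Kruskal stress-1).

    SMACOF with isotonic regression of the disparities, best of
    ``n_starts`` random initializations.  Returns (coordinates, stress-1,
    converged flag).
    """
    D = np.asarray(dissimilarity, dtype=float)
    if len(D) < 3:
        raise ValueError("need at least 3 items")
    mds = MDS(
        n_components=k,
        metric_mds=False,
        n_init=n_starts,
        init="random",
        max_iter=max_iter,
        eps=tol,
        metric="precomputed",
        random_state=seed,
        normalized_stress=True,
    )
    coords = mds.fit_transform(D)
    converged = mds.n_iter_ < max_iter
    return coords, float(mds.stress_), bool(converged)


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def chisq_yates(
    table: np.ndarray, clamp: bool = True
) -> tuple[float, int, float]:
    """2x2 chi-square with Yates continuity correction.

    X^2 = sum (max(|O-E| - 0.5, 0))^2 / E over the four cells (the
    correction is clamped so it never overshoots past zero); p from the
    chi-square upper tail with 1 df.  ``clamp=False`` gives the
    uncorrected-overshoot variant for comparison.
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (O < 0).any():
        raise ValueError("counts must be non-negative")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    n = O.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in 2x2 table")
    E = np.outer(row, col) / n
    adj = np.abs(O - E) - 0.5
    if clamp:
        adj = np.maximum(adj, 0.0)
    x2 = float((adj**2 / E).sum())
    p = float(stats.chi2.sf(x2, df=1))
    return x2, 1, p


def wilcoxon_signed_rank(differences: Sequence[float]) -> tuple[float, int, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped, ties mid-ranked; T is the smaller of
    the two signed-rank sums.  Exact p for n <= 25, normal approximation
    with continuity correction above.  All-zero differences are a
    degenerate case (T=0, p=1).
    """
    d = np.asarray(differences, dtype=float)
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all differences are zero; degenerate Wilcoxon test")
        return 0.0, 0, 1.0
    if len(nz) < 5:
        raise ValueError("need at least 5 non-zero differences")
    method = "exact" if len(nz) <= 25 and not _has_ties(nz) else "approx"
    if method == "exact":
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=False, method="exact")
    else:
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=True, method="approx")
    ranks = stats.rankdata(np.abs(nz))
    t_plus = ranks[nz > 0].sum()
    t_minus = ranks[nz < 0].sum()
    T = float(min(t_plus, t_minus))
    return T, len(nz), float(res.pvalue)


def _has_ties(d: np.ndarray) -> bool:
    a = np.abs(d)
    return len(np.unique(a)) < len(a)


# ---------------------------------------------------------------------------
# Monthly aggregation
# ---------------------------------------------------------------------------

def _events_frame(events: Sequence[CollectionEvent]) -> pd.DataFrame:
    species = sorted({sp for ev in events for sp in ev.counts})
    rows = []
    for ev in events:
        row = {sp: ev.counts.get(sp, 0) for sp in species}
        row["_when"] = ev.datetime
        row["_cid"] = ev.collection_id
        rows.append(row)
    df = pd.DataFrame(rows).set_index("_cid")
    return df


def monthly_presence(events: Sequence[CollectionEvent]) -> PresenceTable:
    """Per species and month: fraction of collections containing the species.

    Month columns are year-month periods; months without collections are
    NaN / no-data.
    """
    if not events:
        raise ValueError("no events")
    df = _events_frame(events)
    months = df["_when"].dt.to_period("M")
    counts = df.drop(columns="_when")
    present = counts > 0
    frac = present.groupby(months).mean().T  # species x month
    frac.columns = frac.columns.astype(str)
    bins = frac.map(presence_bin)
    return PresenceTable(fractions=frac, bins=bins)


def monthly_mean_matrix(events: Sequence[CollectionEvent]) -> AbundanceMatrix:
    """Month-by-year x species matrix of mean eggs/collection."""
    df = _events_frame(events)
    months = df["_when"].dt.to_period("M")
    counts = df.drop(columns="_when")
    means = counts.groupby(months).mean()
    means.index = means.index.astype(str)
    return AbundanceMatrix(data=means, transform_applied="none")
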