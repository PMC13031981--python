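"""Community statistics: composition, ordination, and correlation analyses.

Implements the analysis chain used for seasonal microzooplankton community
data: relative biomass of the four groups, Bray-Curtis dissimilarity with a
permutational ANOSIM, type-III two-way ANOVA on unbalanced season x region
designs, a Pearson co-correlation screen for explanatory variables, z-scored
redundancy analysis (RDA) with a global permutation test, a centroid-distance
outlier rule in RDA space, and season-stratified grazing-biomass
correlations.

Permutation p-values use the add-one convention p = (1 + #{stat_perm >=
stat_obs}) / (1 + n_perm), so p >= 1/1000 at 999 permutations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .schema import (
    GROUP_COLUMNS,
    ConstantColumnError,
    InputError,
    RankDeficientError,
    UndefinedCompositionError,
)

# ---------------------------------------------------------------------------
# Composition and dissimilarity
# ---------------------------------------------------------------------------


def relative_biomass(table: pd.DataFrame, group_columns=GROUP_COLUMNS) -> pd.DataFrame:
    """Each group's share of the four-group total, per sample (rows sum to 1)."""
    out = table.copy()
    sub = out[list(group_columns)].to_numpy(dtype=float)
    if (sub < 0).any():
        raise InputError("biomass must be non-negative")
    totals = sub.sum(axis=1)
    if (totals <= 0).any():
        bad = list(np.flatnonzero(totals <= 0))
        raise UndefinedCompositionError(
            f"all-zero biomass rows have no composition: rows {bad}"
        )
    out[list(group_columns)] = sub / totals[:, None]
    return out


def bray_curtis(matrix) -> np.ndarray:
    """Bray-Curtis dissimilarity: BC(u,v) = sum|u-v| / sum(u+v).

    Symmetric with a zero diagonal; entries in [0, 1] for non-negative input.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise InputError("expected a samples x variables matrix")
    if (X < 0).any():
        raise InputError("Bray-Curtis requires non-negative entries")
    if (X.sum(axis=1) <= 0).any():
        raise InputError("all-zero rows make Bray-Curtis undefined")
    return squareform(pdist(X, metric="braycurtis"))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_perm: int
    method: str  # "permutation" | "exact"


def _anosim_R(ranks, within, denom):
    between = ~within
    return (ranks[between].mean() - ranks[within].mean()) / denom


def anosim(dissimilarity, grouping, n_perm=999, seed=None, method="permutation"):
    """Clarke's ANOSIM on a square dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks taken over all pairwise dissimilarities with average-rank ties.
    R = 1 at complete separation; R ~ 0 under no group structure.

    ``method="permutation"`` draws ``n_perm`` random label permutations and
    reports p = (1 + #{R_perm >= R_obs}) / (1 + n_perm); ``method="exact"``
    enumerates all label orderings (feasible for small n) and reports the
    exact proportion with R_perm >= R_obs.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError("dissimilarity must be square")
    labels = np.asarray(grouping)
    n = D.shape[0]
    if labels.shape != (n,):
        raise InputError("grouping length must match the matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or (counts < 2).any():
        raise InputError("need >= 2 groups with >= 2 members each")

    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(D[iu, ju], method="average")
    denom = n * (n - 1) / 4.0
    codes = np.searchsorted(uniq, labels)
    r_obs = _anosim_R(ranks, codes[iu] == codes[ju], denom)

    if method == "exact":
        count = 0
        total = 0
        for perm in itertools.permutations(codes):
            p = np.asarray(perm)
            r = _anosim_R(ranks, p[iu] == p[ju], denom)
            count += r >= r_obs - 1e-12
            total += 1
        return AnosimResult(R=float(r_obs), p_value=count / total,
                            n_perm=total, method="exact")
    if method != "permutation":
        raise InputError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(codes)
        r = _anosim_R(ranks, p[iu] == p[ju], denom)
        count += r >= r_obs - 1e-12
    return AnosimResult(
        R=float(r_obs),
        p_value=(1 + count) / (1 + n_perm),
        n_perm=n_perm,
        method="permutation",
    )


# ---------------------------------------------------------------------------
# Type-III two-way ANOVA
# ---------------------------------------------------------------------------


def two_way_anova_type3(
    response,
    factor_season,
    factor_region,
    exclude_outliers=True,
    outlier_flags=None,
) -> pd.DataFrame:
    """Season x region ANOVA with type-III (marginal) sums of squares.

    Sum-to-zero contrasts, interaction included — the appropriate marginal
    tests for unbalanced designs. Rows flagged as outliers are dropped first
    when requested. Terms made inestimable by empty cells are reported with
    NaN statistics rather than raising.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(response, dtype=float),
            "season": np.asarray(factor_season, dtype=object),
            "region": np.asarray(factor_region, dtype=object),
        }
    )
    if exclude_outliers and outlier_flags is not None:
        df = df[~np.asarray(outlier_flags, dtype=bool)]
    if df.empty:
        raise InputError("no observations left after outlier exclusion")
    model = ols("y ~ C(season, Sum) * C(region, Sum)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on NaN F for df=0
        table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(
        index={
            "C(season, Sum)": "season",
            "C(region, Sum)": "region",
            "C(season, Sum):C(region, Sum)": "season:region",
        }
    )
    return table.drop(index="Intercept", errors="ignore")


# ---------------------------------------------------------------------------
# Explanatory-variable screening and z-scoring
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    retained: list
    eliminated: list
    clusters: list  # lists of mutually co-correlated column names
    correlations: pd.DataFrame  # pairwise r among explanatory columns
    n_complete: int


def pearson_screen(env: pd.DataFrame, response: pd.DataFrame,
                   r_threshold=0.70, alpha=0.05) -> ScreenResult:
    """Drop co-correlated explanatory variables before ordination.

    Pairs with |r| > ``r_threshold`` and p < ``alpha`` (complete cases only)
    form co-correlation clusters (connected components); within each cluster
    the variable with the highest cumulative |r| against the response columns
    is retained and the rest are eliminated.
    """
    env = env.copy()
    response = response.copy()
    complete = pd.concat([env, response], axis=1).dropna().index
    if len(complete) < 3:
        raise InputError(f"only {len(complete)} complete rows; need >= 3")
    env = env.loc[complete]
    response = response.loc[complete]
    cols = list(env.columns)
    k = len(cols)

    r_mat = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a, b in itertools.combinations(cols, 2):
        r, p = stats.pearsonr(env[a], env[b])
        r_mat.loc[a, b] = r_mat.loc[b, a] = r
        if abs(r) > r_threshold and p < alpha:
            parent[find(a)] = find(b)

    clusters: dict = {}
    for c in cols:
        clusters.setdefault(find(c), []).append(c)

    retained, eliminated, cluster_list = [], [], []
    for members in clusters.values():
        if len(members) == 1:
            retained.append(members[0])
            continue
        cluster_list.append(list(members))
        score = {
            m: float(sum(abs(stats.pearsonr(env[m], response[rc])[0])
                         for rc in response.columns))
            for m in members
        }
        best = max(members, key=lambda m: score[m])  # ties: first in order
        retained.append(best)
        eliminated.extend(m for m in members if m != best)

    retained = [c for c in cols if c in retained]  # preserve input order
    return ScreenResult(
        retained=retained,
        eliminated=eliminated,
        clusters=cluster_list,
        correlations=r_mat,
        n_complete=len(complete),
    )


def zscore(columns: pd.DataFrame, ddof=1) -> pd.DataFrame:
    """Standardize every column to mean 0, SD 1 (sample SD by default)."""
    out = columns.astype(float).copy()
    for c in out.columns:
        sd = out[c].std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ConstantColumnError(f"column {c!r} has zero variance")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Redundancy analysis
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Constrained ordination of a response matrix on explanatory variables.

    ``site_scores`` are the centered responses projected onto the constrained
    axes (weighted-average-style scores, so a sample's position reflects its
    actual composition); ``lc_scores`` are the fitted-value (linear
    combination) scores. ``loadings`` are correlations of each explanatory
    variable with the lc axes.
    """

    site_scores: np.ndarray
    lc_scores: np.ndarray
    loadings: pd.DataFrame
    response_scores: pd.DataFrame
    eigenvalues: np.ndarray
    constrained_fraction: float
    p_value: float
    n_axes: int
    n_perm: int


def rda(response, explanatory, n_perm=999, seed=None) -> OrdinationResult:
    """Redundancy analysis with a global permutation test.

    The centered response Y is regressed on the (already z-scored) centered
    explanatory matrix X; the fitted values are eigen-decomposed to give the
    constrained axes. ``constrained_fraction`` is the share of total response
    variance captured by the fit, trace(Yhat'Yhat)/trace(Y'Y) — the
    multivariate R². Significance comes from permuting rows of X and
    recomputing that statistic.
    """
    Y = np.asarray(response, dtype=float)
    if isinstance(explanatory, pd.DataFrame):
        x_names = list(explanatory.columns)
        X = explanatory.to_numpy(dtype=float)
    else:
        X = np.asarray(explanatory, dtype=float)
        x_names = [f"x{i}" for i in range(X.shape[1])]
    if isinstance(response, pd.DataFrame):
        y_names = list(response.columns)
    else:
        y_names = [f"y{i}" for i in range(Y.shape[1])]
    n, m = Y.shape
    q = X.shape[1]
    if X.shape[0] != n:
        raise InputError("response and explanatory row counts differ")
    if n < q + 2:
        raise InputError(f"need at least q+2 = {q + 2} samples, got {n}")
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < q:
        raise RankDeficientError(
            "explanatory matrix is rank deficient; remove co-correlated "
            "variables (see pearson_screen)"
        )
    total_ss = float((Yc**2).sum())
    if total_ss == 0:
        raise InputError("response has zero variance")

    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    tol = max(n, m) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    k = int((s > tol).sum())
    k = max(k, 1)
    eigenvalues = s[:k] ** 2 / (n - 1)
    constrained = float((s**2).sum() / total_ss)

    V = Vt[:k].T  # response loadings (species scores), m x k
    site = Yc @ V
    lc = U[:, :k] * s[:k]

    load = np.zeros((q, k))
    for j in range(q):
        xs = Xc[:, j]
        sx = xs.std(ddof=1)
        for a in range(k):
            sa = lc[:, a].std(ddof=1)
            load[j, a] = (
                np.cov(xs, lc[:, a], ddof=1)[0, 1] / (sx * sa)
                if sx > 0 and sa > 0
                else 0.0
            )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Xp = Xc[rng.permutation(n)]
        Q, _ = np.linalg.qr(Xp)
        frac = float(((Q.T @ Yc) ** 2).sum() / total_ss)
        count += frac >= constrained - 1e-12
    p = (1 + count) / (1 + n_perm)

    axis_names = [f"RDA{a + 1}" for a in range(k)]
    return OrdinationResult(
        site_scores=site,
        lc_scores=lc,
        loadings=pd.DataFrame(load, index=x_names, columns=axis_names),
        response_scores=pd.DataFrame(V, index=y_names, columns=axis_names),
        eigenvalues=eigenvalues,
        constrained_fraction=constrained,
        p_value=p,
        n_axes=k,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# RDA-space outlier rule
# ---------------------------------------------------------------------------


def rda_outliers(site_scores, season_labels, ratio=0.5, sd_mult=2.5,
                 n_axes=None) -> pd.DataFrame:
    """Centroid-distance outlier detection in ordination space.

    For each sample, the Euclidean distance to its own season's centroid
    (d_own) and to the opposite season's (d_opp) is computed over the first
    ``n_axes`` constrained axes (all by default). A sample is an outlier if
    it is more than 50% closer to the opposite centroid (d_opp < ratio *
    d_own) or more than ``sd_mult`` standard deviations beyond its season's
    mean centroid distance (d_own > mean_own + sd_mult * sd_own).
    """
    S = np.asarray(site_scores, dtype=float)
    if S.ndim != 2:
        raise InputError("site scores must be 2D")
    labels = np.asarray(season_labels)
    if labels.shape[0] != S.shape[0]:
        raise InputError("season labels must match site scores")
    seasons = np.unique(labels)
    if seasons.size != 2:
        raise InputError(f"need exactly 2 seasons, got {list(seasons)}")
    for sn in seasons:
        if (labels == sn).sum() < 3:
            raise InputError(f"season {sn!r} has fewer than 3 samples")
    if n_axes is not None:
        S = S[:, :n_axes]

    centroids = {sn: S[labels == sn].mean(axis=0) for sn in seasons}
    opposite = {seasons[0]: seasons[1], seasons[1]: seasons[0]}
    d_own = np.array(
        [np.linalg.norm(S[i] - centroids[labels[i]]) for i in range(len(S))]
    )
    d_opp = np.array(
        [np.linalg.norm(S[i] - centroids[opposite[labels[i]]])
         for i in range(len(S))]
    )
    mean_own = {sn: d_own[labels == sn].mean() for sn in seasons}
    sd_own = {sn: d_own[labels == sn].std(ddof=1) for sn in seasons}

    closer = d_opp < ratio * d_own
    beyond = np.array(
        [d_own[i] > mean_own[labels[i]] + sd_mult * sd_own[labels[i]]
         for i in range(len(S))]
    )
    return pd.DataFrame(
        {
            "season": labels,
            "d_own": d_own,
            "d_opp": d_opp,
            "own_season_distance_sd": [sd_own[sn] for sn in labels],
            "closer_to_opposite": closer,
            "beyond_sd": beyond,
            "outlier": closer | beyond,
        }
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


@dataclass
class SummaryResult:
    by_stratum: pd.DataFrame  # (season, region) x statistics
    group_shares: pd.Series  # grand mean share per group
    winter_summer_ratio: pd.Series  # per region + "overall"
    n_excluded: int


def season_region_summary(table: pd.DataFrame, exclude_outliers=True,
                          outlier_col="outlier") -> SummaryResult:
    """Mean, SD and SE of each group and of the total per (season, region).

    Flagged outlier samples are excluded from every reported mean when
    requested. Single-sample strata report NaN SD; winter:summer total-mean
    ratios are reported per region and overall.
    """
    df = table.copy()
    n_excl = 0
    if exclude_outliers and outlier_col in df.columns:
        flags = df[outlier_col].astype(bool)
        n_excl = int(flags.sum())
        df = df[~flags]
    if df.empty:
        raise InputError("no samples left to summarize")
    groups = list(GROUP_COLUMNS)
    df = df.copy()
    df["total"] = df[groups].sum(axis=1)

    records = []
    for (season, region), sub in df.groupby(["season", "region"], sort=True):
        rec = {"season": season, "region": region, "n": len(sub)}
        for col in groups + ["total"]:
            rec[f"{col}_mean"] = sub[col].mean()
            rec[f"{col}_sd"] = sub[col].std(ddof=1) if len(sub) > 1 else float("nan")
            rec[f"{col}_se"] = (
                sub[col].std(ddof=1) / math.sqrt(len(sub))
                if len(sub) > 1 else float("nan")
            )
        records.append(rec)
    by_stratum = pd.DataFrame(records).set_index(["season", "region"])

    shares = df[groups].sum() / df[groups].sum().sum()
    shares["dino_total"] = shares["dino_small"] + shares["dino_large"]
    shares["cil_total"] = shares["cil_small"] + shares["cil_large"]

    ratios = {}
    for region, sub in df.groupby("region"):
        w = sub.loc[sub["season"] == "winter", "total"].mean()
        s = sub.loc[sub["season"] == "summer", "total"].mean()
        ratios[region] = w / s if s and not math.isnan(s) else float("nan")
    w = df.loc[df["season"] == "winter", "total"].mean()
    s = df.loc[df["season"] == "summer", "total"].mean()
    ratios["overall"] = w / s if s else float("nan")

    return SummaryResult(
        by_stratum=by_stratum,
        group_shares=shares,
        winter_summer_ratio=pd.Series(ratios),
        n_excluded=n_excl,
    )


def grazing_biomass_correlation(
    table: pd.DataFrame,
    rate_col="grazing_rate",
    stratify_by_season=True,
    exclude_outliers=True,
    outlier_col="outlier",
) -> pd.DataFrame:
    """Pearson r between grazing rate and biomass, per season stratum.

    Correlates the rate column against total biomass, each of the four
    groups, and the taxon totals. Samples with missing (undetermined) rates
    are dropped; strata with fewer than 3 complete pairs are skipped with a
    warning. Two-sided p-values via the t transformation with n-2 df.
    """
    df = table.copy()
    if exclude_outliers and outlier_col in df.columns:
        df = df[~df[outlier_col].astype(bool)]
    df = df[df[rate_col].notna()]
    groups = list(GROUP_COLUMNS)
    df["total"] = df[groups].sum(axis=1)
    df["dino_total"] = df["dino_small"] + df["dino_large"]
    df["cil_total"] = df["cil_small"] + df["cil_large"]
    targets = ["total", "dino_total", "cil_total"] + groups

    strata = df.groupby("season") if stratify_by_season else [("all", df)]
    rows = []
    for name, sub in strata:
        if len(sub) < 3:
            warnings.warn(f"stratum {name!r} has fewer than 3 pairs; skipped",
                          stacklevel=2)
            continue
        for col in targets:
            r, p = stats.pearsonr(sub[col], sub[rate_col])
            rows.append({"stratum": name, "biomass": col, "r": float(r),
                         "p_value": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
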