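"""Inference layer: permutation tests, phylogenetic GLS, and classical tests.

Permutation p-values follow the add-one rule throughout,

    p = (number of permuted statistics >= observed + 1) / (B + 1) ,

with an inclusive (>=) comparison, so p is never smaller than 1/(B+1) and
never exactly zero.

The Mantel test correlates the off-diagonal entries of two distance
matrices (Pearson's r) and builds its null by relabeling one matrix. Two
permutation schemes are available: ``uniform`` (all label permutations
equally likely — the classical Mantel null) and ``phylogenetic``
(proximity-weighted label exchanges: a label is more likely to land on a
phylogenetically nearby tip, concentrating the null on permutations that
respect the tree's dependence structure).

The group-ratio test compares mean (possibly phylogenetic-distance-
adjusted) divergence between two groups of within-group pairs. Group labels
of the *populations* — not the pairs — are shuffled, so the pair-level
dependence induced by shared populations is preserved under the null.

PGLS (phylogenetic generalized least squares) fits y = X beta + eps with
Cov(eps) = sigma^2 V, V the Brownian covariance of the tree, via whitening
with the Cholesky factor of V. With a binary domestication indicator in X
this is a phylogenetic ANOVA; adding a growth-state covariate isolates the
independent effect of domestication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import DistanceMatrix
from .normalize import ProfileTable, SampleTable
from .treeio import Phylogeny, brownian_covariance, patristic_distance_matrix

__all__ = [
    "PermutationResult",
    "MantelResult",
    "PGLSFit",
    "mantel_test",
    "group_ratio_permutation_test",
    "oneway_anova_per_metabolite",
    "bartlett_test",
    "pgls_anova",
    "domestication_signature_scan",
    "fisher_exact_overlap",
]


# ---------------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed: float
    n_permutations: int
    exceed_count: int
    p_value: float
    seed: int | None
    scheme: str = "uniform"
    n_resampled: int = 0

    def __post_init__(self) -> None:
        expected = (self.exceed_count + 1) / (self.n_permutations + 1)
        if abs(self.p_value - expected) > 1e-12:
            raise ValueError("p_value inconsistent with the add-one rule")


@dataclass
class MantelResult:
    r: float
    n_permutations: int
    exceed_count: int
    p_value: float
    seed: int | None
    scheme: str = "uniform"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r out of range")


@dataclass
class PGLSFit:
    """GLS coefficient table plus fit metadata."""

    params: pd.DataFrame  # index: term; columns: estimate, se, t, p
    sigma2: float
    n: int
    df_resid: int
    structure: str = "brownian"

    def coef(self, term: str) -> pd.Series:
        return self.params.loc[term]


# ---------------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("constant off-diagonal values; correlation undefined")
    return float(xc @ yc / denom)


def _phylo_weighted_permutation(
    rng: np.random.Generator, weights: np.ndarray
) -> np.ndarray:
    """Draw a permutation where label i preferentially maps to nearby tips.

    ``weights[i, j]`` is the (unnormalized) probability that label i is
    placed at position j; labels are assigned one at a time in random order,
    sampling among the still-free positions.
    """
    n = weights.shape[0]
    perm = np.empty(n, dtype=int)
    free = np.ones(n, dtype=bool)
    for i in rng.permutation(n):
        w = weights[i] * free
        total = w.sum()
        if total <= 0:
            w = free.astype(float)
            total = w.sum()
        j = rng.choice(n, p=w / total)
        perm[i] = j
        free[j] = False
    return perm


def mantel_test(
    X: DistanceMatrix,
    Y: DistanceMatrix,
    n_permutations: int = 100_000,
    scheme: str = "uniform",
    tree: Phylogeny | None = None,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices with a permutation null.

    The observed statistic is Pearson's r over the vectorized upper
    triangles; the null relabels ``Y`` ``n_permutations`` times and the
    one-sided p-value counts permuted r >= observed (add-one rule). The
    ``phylogenetic`` scheme requires ``tree`` and weights label exchanges by
    ``exp(-d/mean(d))`` of the patristic distance d between the original and
    proposed tip positions.
    """
    if X.labels != Y.labels:
        raise ValueError("distance matrices must share the same label order")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = len(X.labels)
    iu = np.triu_indices(n, k=1)
    x = X.values[iu]
    y = Y.values[iu]
    r_obs = _pearson(x, y)

    rng = np.random.default_rng(seed)
    if scheme == "uniform":
        perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    elif scheme == "phylogenetic":
        if tree is None:
            raise ValueError("phylogenetic scheme requires a tree")
        _, D = patristic_distance_matrix(tree, X.labels)
        off = D[np.triu_indices(n, 1)]
        scale = off.mean() if off.mean() > 0 else 1.0
        weights = np.exp(-D / scale)
        perms = np.array(
            [_phylo_weighted_permutation(rng, weights) for _ in range(n_permutations)]
        )
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    # vectorized permuted upper triangles of Y
    yp = Y.values[perms[:, iu[0]], perms[:, iu[1]]]
    yc = yp - yp.mean(axis=1, keepdims=True)
    xc = x - x.mean()
    denom = np.sqrt((xc @ xc) * np.sum(yc**2, axis=1))
    r_perm = (yc @ xc) / denom
    exceed = int(np.sum(r_perm >= r_obs - 1e-15))
    p = (exceed + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, n_permutations=n_permutations,
                        exceed_count=exceed, p_value=p, seed=seed, scheme=scheme)


# ---------------------------------------------------------------------------------
# group-ratio permutation test
# ---------------------------------------------------------------------------------


def _within_group_means(
    D: np.ndarray, E: np.ndarray, membership: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean eligible within-group pair value for each permuted assignment.

    ``membership`` is a (B, n) boolean matrix of group membership; returns
    (means, pair counts) per row.
    """
    M = membership.astype(float)
    DE = D * E
    sums = np.einsum("bi,ij,bj->b", M, DE, M) / 2.0
    counts = np.einsum("bi,ij,bj->b", M, E.astype(float), M) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1e-300), np.nan)
    return means, counts


def _folded_ratio(m1, m2):
    """max(m1/m2, m2/m1) elementwise; 1 when both are zero, inf when one is."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(m1 >= m2, m1 / m2, m2 / m1)
    r = np.where((m1 == 0) & (m2 == 0), 1.0, r)
    if r.ndim == 0:
        return float(r)
    return r


def group_ratio_permutation_test(
    div: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 100_000,
    seed: int | None = None,
    eligible_pairs: Sequence[tuple[str, str]] | None = None,
    max_resample_rounds: int = 100,
) -> PermutationResult:
    """Ratio-of-mean-divergences test with population-label shuffling.

    The statistic is the ratio of the two groups' mean within-group
    divergences, reported with the larger observed mean in the numerator
    (so the observed ratio is >= 1). To keep the test exact under
    exchangeability, permuted statistics are orientation-invariant as well:
    each permuted ratio is folded as max(r, 1/r) before comparison, so a
    group assignment that is extreme in *either* direction counts against
    the observed one. Group labels are shuffled across populations
    (sampling without
    replacement); permutations that leave either group without an eligible
    pair are redrawn and their number reported. ``eligible_pairs``
    optionally restricts which population pairs may contribute (e.g. only
    same-clade domesticated pairs); the restriction is a fixed property of
    the population pair and survives the shuffle.
    """
    labels = div.labels
    missing = [l for l in labels if l not in groups]
    if missing:
        raise KeyError(f"populations without a group label: {missing}")
    names = sorted(set(groups[l] for l in labels))
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    g1, g2 = names
    n = len(labels)
    assign = np.array([groups[l] == g1 for l in labels])

    if eligible_pairs is None:
        E = ~np.eye(n, dtype=bool)
    else:
        E = np.zeros((n, n), dtype=bool)
        idx = {l: i for i, l in enumerate(labels)}
        for a, b in eligible_pairs:
            E[idx[a], idx[b]] = E[idx[b], idx[a]] = True

    D = div.values
    m1, c1 = _within_group_means(D, E, assign[None, :])
    m2, c2 = _within_group_means(D, E, ~assign[None, :])
    if c1[0] < 1 or c2[0] < 1:
        raise ValueError("each group needs at least one eligible within-group pair")
    ratio_obs = _folded_ratio(m1[0], m2[0])

    rng = np.random.default_rng(seed)
    ratios = np.full(n_permutations, np.nan)
    pending = np.arange(n_permutations)
    n_resampled = 0
    for _ in range(max_resample_rounds):
        if len(pending) == 0:
            break
        B = len(pending)
        perm_assign = np.empty((B, n), dtype=bool)
        for b in range(B):
            perm_assign[b] = assign[rng.permutation(n)]
        pm1, pc1 = _within_group_means(D, E, perm_assign)
        pm2, pc2 = _within_group_means(D, E, ~perm_assign)
        ok = (pc1 >= 1) & (pc2 >= 1)
        ratios[pending[ok]] = _folded_ratio(pm1[ok], pm2[ok])
        n_resampled += int((~ok).sum())
        pending = pending[~ok]
    if len(pending):
        raise RuntimeError(
            "could not find valid permutations; groups too small for the pair filter"
        )
    exceed = int(np.sum(ratios >= ratio_obs - 1e-15))
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationResult(
        observed=float(ratio_obs), n_permutations=n_permutations,
        exceed_count=exceed, p_value=p, seed=seed, scheme="uniform",
        n_resampled=n_resampled,
    )


# ---------------------------------------------------------------------------------
# per-metabolite classical tests
# ---------------------------------------------------------------------------------


def oneway_anova_per_metabolite(
    table: SampleTable, grouping: str = "population"
) -> pd.DataFrame:
    """One-way ANOVA of normalized log levels across groups, per metabolite.

    Returns a frame indexed by metabolite with F, degrees of freedom, and p;
    metabolites where F is undefined (no variance anywhere) get NaN and an
    ``undefined`` flag.
    """
    bio = table.bio
    if bio.isna().any().any():
        raise ValueError("ANOVA requires a complete table; impute first")
    labels = table.meta.loc[bio.index, grouping]
    if labels.nunique() < 2:
        raise ValueError("need at least two groups")
    logged = np.log(bio)
    out = []
    group_arrays = {g: logged.loc[labels == g] for g in labels.unique()}
    k = len(group_arrays)
    n_total = len(logged)
    for metabolite in logged.columns:
        samples = [g[metabolite].to_numpy() for g in group_arrays.values()]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            out.append(dict(metabolite=metabolite, F=np.nan, df_between=k - 1,
                            df_within=n_total - k, p=np.nan, undefined=True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*samples)
        out.append(dict(metabolite=metabolite, F=float(F), df_between=k - 1,
                        df_within=n_total - k, p=float(p), undefined=not np.isfinite(F)))
    return pd.DataFrame(out).set_index("metabolite")


def bartlett_test(fold_change_table: pd.DataFrame) -> tuple[float, float]:
    """Bartlett's homogeneity-of-variances test across metabolites.

    Each metabolite's fold-change vector (over labels) is one group; the
    test asks whether metabolites differ in the spread of their fold
    changes. Returns (chi-square statistic, p-value).
    """
    groups = [fold_change_table[c].dropna().to_numpy() for c in fold_change_table.columns]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 metabolites with >= 2 values each")
    if any(np.var(g, ddof=1) == 0 for g in groups):
        raise ValueError("zero-variance metabolite; Bartlett statistic undefined")
    statistic, p = stats.bartlett(*groups)
    return float(statistic), float(p)


# ---------------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------------


def pgls_anova(
    y: pd.Series,
    design: pd.DataFrame,
    V: np.ndarray,
    jitter: float = 1e-8,
    structure: str = "brownian",
) -> PGLSFit:
    """Generalized least squares with a phylogenetic error covariance.

    Solves beta = (X' V^-1 X)^-1 X' V^-1 y by Cholesky whitening; an
    intercept column is prepended automatically. sigma^2 is the residual
    quadratic form over (n - p); coefficient p-values are two-sided t-tests
    on n - p degrees of freedom. Singular V (zero-length branches) gets a
    ridge of ``jitter * mean(diag(V))`` with a warning.
    """
    if not y.index.equals(design.index):
        design = design.loc[y.index]
    n = len(y)
    X = np.column_stack([np.ones(n), design.to_numpy(dtype=float)])
    names = ["intercept"] + list(design.columns)
    p = X.shape[1]
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    V = np.asarray(V, dtype=float)
    if V.shape != (n, n):
        raise ValueError("covariance shape does not match observation count")
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        ridge = jitter * float(np.mean(np.diag(V)))
        warnings.warn(
            f"singular phylogenetic covariance; adding ridge {ridge:.3g}",
            stacklevel=2,
        )
        try:
            L = np.linalg.cholesky(V + ridge * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance not positive definite even after jitter") from exc
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y.to_numpy(dtype=float))
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "t": t, "p": pvals}, index=names
    )
    return PGLSFit(params=params, sigma2=sigma2, n=n, df_resid=df, structure=structure)


def domestication_signature_scan(
    profiles: ProfileTable,
    tree: Phylogeny,
    groups: Mapping[str, str],
    covariate: pd.Series | None = None,
    alpha: float = 0.05,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-metabolite phylogenetic ANOVA for a convergent group effect.

    Fits, for every metabolite, a PGLS of the population-mean level on a
    domesticated-vs-wild indicator (optionally plus a covariate such as
    average growth state) under the tree's Brownian covariance, and reports
    the group coefficient's estimate, sign, and p-value, with a significance
    flag at ``alpha``. ``exclude`` drops named populations from the fit
    (robustness reruns) without touching the other populations' values.
    """
    labels = [l for l in profiles.labels if l not in set(exclude)]
    if len(labels) < 3:
        raise ValueError("need at least three populations")
    missing = [l for l in labels if l not in groups]
    if missing:
        raise KeyError(f"populations without group labels: {missing}")
    _, V = brownian_covariance(tree, labels)
    indicator = pd.Series(
        [1.0 if groups[l] == "domesticated" else 0.0 for l in labels], index=labels,
        name="domesticated",
    )
    design = indicator.to_frame()
    if covariate is not None:
        design["covariate"] = covariate.loc[labels].astype(float)
    levels = profiles.levels.loc[labels]
    rows = []
    for metabolite in levels.columns:
        fit = pgls_anova(levels[metabolite], design, V)
        coef = fit.coef("domesticated")
        rows.append(
            dict(
                metabolite=metabolite,
                estimate=coef["estimate"],
                se=coef["se"],
                t=coef["t"],
                p=coef["p"],
                sign=int(np.sign(coef["estimate"])),
                significant=bool(coef["p"] < alpha),
            )
        )
    return pd.DataFrame(rows).set_index("metabolite")


# ---------------------------------------------------------------------------------
# overlap test
# ---------------------------------------------------------------------------------


def fisher_exact_overlap(
    set_a: set | Sequence, set_b: set | Sequence, universe: set | Sequence
) -> tuple[float, float]:
    """Two-sided Fisher's exact test for overlap of two sets in a universe.

    Builds the 2x2 membership table (in/out of each set) and returns
    (odds ratio, p). Elements outside the universe raise.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    stray = (a | b) - universe
    if stray:
        raise ValueError(f"elements outside the universe: {sorted(stray)}")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(universe) - both - only_a - only_b
    odds, p = stats.fisher_exact([[both, only_a], [only_b, neither]], alternative="two-sided")
    return float(odds), float(p)
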