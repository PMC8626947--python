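"""Community-ecology and differential-abundance statistics.

Ordination and matrix-correlation steps follow the standard vegan-style
workflow: Hellinger standardization, Bray-Curtis dissimilarity,
principal coordinates analysis, Mantel and PERMANOVA permutation tests
(delegated to scikit-bio, seeded), and sample-accumulation curves.

Differential abundance across depth levels uses a negative-binomial GLM
likelihood-ratio test: median-of-ratios size factors, per-vOTU
dispersion by Cox-Reid-adjusted profile maximum likelihood (no
shrinkage across vOTUs, no outlier replacement), a full model with a
depth-level factor against an intercept-only reduced model, chi-square
asymptotics and Benjamini-Hochberg adjustment.  Significant vOTUs are
grouped by the depth of their peak Z-transformed abundance, and trait
enrichment per group is an upper-tail hypergeometric test.

Matrices are oriented samples x vOTUs throughout this module (the
transpose of the detection table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from skbio import DistanceMatrix
from skbio.stats import distance as skbio_distance
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p: float
    n_perm: int


@dataclass
class DAResult:
    """Per-vOTU likelihood-ratio test results plus group assignments."""

    table: pd.DataFrame  # columns: lrt, df, p, padj, dispersion
    significant: list[str] = field(default_factory=list)
    groups: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class EnrichmentResult:
    group_id: int
    k: int
    n: int
    K: int
    N: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def hellinger(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hellinger standardization: sqrt of row-relative abundances."""
    totals = matrix.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero sample(s) left as zeros", int(zero.sum()))
        totals = totals.replace(0, 1)
    return np.sqrt(matrix.div(totals, axis=0))


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows."""
    d = pdist(matrix.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(np.nan_to_num(d)), ids=[str(i) for i in matrix.index])


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Returns sample coordinates on the positive axes and the full vector
    of relative eigenvalues (negative eigenvalues retained in the
    report, not in the coordinates).
    """
    res = _skbio_pcoa(dm, method="eigh", dimensions=dm.shape[0], warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    rel = eig / np.abs(eig).sum() if np.abs(eig).sum() else eig
    coords = res.samples
    coords.index = list(dm.ids)
    keep = [c for i, c in enumerate(coords.columns) if eig[i] > 0]
    return coords[keep], rel


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int | None = None
) -> MantelResult:
    """One-sided (upper) Mantel test with Pearson correlation."""
    for name, d in (("first", d1), ("second", d2)):
        if np.allclose(d.condensed_form(), d.condensed_form()[0]):
            raise ValueError(f"{name} distance matrix has zero variance")
    r, p, _ = skbio_distance.mantel(
        d1, d2, method="pearson", permutations=n_perm, alternative="greater", seed=seed
    )
    return MantelResult(float(r), float(p), n_perm)


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """Permutational multivariate ANOVA (one-way) on a distance matrix."""
    labels = pd.Series(list(groups))
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if len(labels) - len(counts) < 1:
        raise ValueError("PERMANOVA requires residual degrees of freedom")
    res = skbio_distance.permanova(dm, labels.to_numpy(), permutations=n_perm, seed=seed)
    return PermanovaResult(float(res["test statistic"]), float(res["p-value"]), n_perm)


def accumulation_curve(
    presence: pd.DataFrame, n_perm: int = 100, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-accumulation curve of distinct detected vOTUs.

    ``presence`` is samples x vOTUs (boolean or abundance; nonzero means
    detected).  Returns the mean cumulative richness per number of
    samples and the per-permutation curves.
    """
    rng = np.random.default_rng(seed)
    mat = presence.to_numpy() > 0
    n = mat.shape[0]
    curves = np.zeros((n_perm, n), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen = np.zeros(mat.shape[1], dtype=bool)
        for k, s in enumerate(order):
            seen |= mat[s]
            curves[p, k] = seen.sum()
    return curves.mean(axis=0), curves


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (computed over vOTUs with
    all-positive counts; falls back to library-size proportions when no
    such vOTU exists)."""
    pos = counts[(counts > 0).all(axis=1)]
    if len(pos):
        logg = np.log(pos)
        ref = logg.mean(axis=1)
        sf = np.exp((logg.sub(ref, axis=0)).median(axis=0))
    else:
        logger.warning("no all-positive vOTU rows; using library-size factors")
        tot = counts.sum(axis=0).astype(float)
        sf = tot / np.exp(np.log(tot.replace(0, 1)).mean())
    return sf


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    size = 1.0 / alpha
    return float(stats.nbinom.logpmf(y, size, size / (size + mu)).sum())


def _fit_nb(y, X, offset, alpha):
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset)
    return model.fit(maxiter=50, tol=1e-8)


def _cr_profile_alpha(y, X, offset, prior=None) -> float:
    """Cox-Reid-adjusted profile ML dispersion for one vOTU.

    The adjustment (-0.5 log det X'WX) reduces the downward bias of the
    plain ML estimate at small sample sizes.  With ``prior`` =
    (log_center, variance) the objective is penalized by a log-normal
    prior, giving the maximum-a-posteriori estimate used for dispersion
    moderation.  Falls back to a method-of-moments estimate when
    optimization fails; floored at 1e-8.
    """
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    mu0 = np.clip(pois.fittedvalues, 1e-8, None)
    resid = ((y - mu0) ** 2 - mu0) / mu0**2
    mom = max(np.mean(resid), 1e-3)

    def neg_apl(log_alpha: float) -> float:
        alpha = np.exp(log_alpha)
        try:
            fit = _fit_nb(y, X, offset, alpha)
        except Exception:
            return np.inf
        mu = np.clip(fit.fittedvalues, 1e-8, None)
        W = mu / (1.0 + alpha * mu)
        xtwx = (X * W[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        out = -(_nb_loglik(y, mu, alpha) - 0.5 * logdet)
        if prior is not None:
            center, var = prior
            out += (log_alpha - center) ** 2 / (2.0 * var)
        return out

    try:
        res = minimize_scalar(
            neg_apl,
            bounds=(np.log(1e-8), np.log(50.0)),
            method="bounded",
            options={"xatol": 5e-2},
        )
        if np.isfinite(res.fun):
            return max(float(np.exp(res.x)), 1e-8)
    except Exception:  # pragma: no cover - defensive
        pass
    return max(mom, 1e-8)


def _dispersion_trend(mu_bar: np.ndarray, alphas: np.ndarray):
    """Parametric mean-dispersion trend a(mu) = a0 + a1/mu.

    Fitted on the log scale by least squares with one round of outlier
    exclusion; returns per-vOTU trend values.  Falls back to the median
    dispersion when the fit degenerates.
    """
    from scipy.optimize import minimize

    log_a = np.log(np.clip(alphas, 1e-6, None))

    def obj(theta, keep):
        a0, a1 = np.exp(theta)
        pred = np.log(a0 + a1 / mu_bar[keep])
        return ((log_a[keep] - pred) ** 2).sum()

    keep = np.ones(len(alphas), dtype=bool)
    theta = np.log([max(np.median(alphas), 1e-3), 1.0])
    for _ in range(2):
        res = minimize(obj, theta, args=(keep,), method="Nelder-Mead")
        if not np.isfinite(res.fun):
            return np.full(len(alphas), np.median(alphas))
        theta = res.x
        a0, a1 = np.exp(theta)
        resid = log_a - np.log(a0 + a1 / mu_bar)
        sd = resid[keep].std()
        if sd == 0:
            break
        keep = np.abs(resid) < 2 * sd
        if keep.sum() < max(10, len(alphas) // 10):
            break
    a0, a1 = np.exp(theta)
    return a0 + a1 / mu_bar


def nb_lrt(
    counts: pd.DataFrame,
    depth_levels,
    alpha_sig: float = 0.05,
    moderate: bool = True,
) -> DAResult:
    """Negative-binomial likelihood-ratio test across depth levels.

    ``counts`` is vOTUs x samples; ``depth_levels`` gives one level per
    sample (in column order).  All-zero vOTU rows are dropped.  The full
    model regresses log mean on a depth-level factor with a
    log-size-factor offset; the reduced model is intercept-only; the LRT
    statistic is referred to chi-square with (levels - 1) degrees of
    freedom and BH-adjusted.

    With ``moderate`` (the default) the per-vOTU dispersions are
    shrunk toward a parametric mean-dispersion trend by a log-normal
    empirical-Bayes prior before testing, as in the standard count-data
    differential-abundance workflow; without it, dispersion-estimation
    noise at typical sample sizes makes the chi-square reference
    measurably anti-conservative.
    """
    from scipy.special import polygamma

    levels = pd.Categorical(list(depth_levels))
    if len(levels.categories) < 2:
        raise ValueError("need at least two depth levels")
    keep = counts.index[(counts > 0).any(axis=1)]
    dropped = len(counts) - len(keep)
    if dropped:
        logger.info("dropped %d all-zero vOTU row(s)", dropped)
    counts = counts.loc[keep]
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy(dtype=float))
    X_full = pd.get_dummies(pd.Series(levels), drop_first=True, dtype=float)
    X_full.insert(0, "const", 1.0)
    X_full = X_full.to_numpy()
    X_red = np.ones((counts.shape[1], 1))
    df = len(levels.categories) - 1
    n, p_full = X_full.shape

    Y = counts.to_numpy(dtype=float)
    genewise = np.empty(len(counts))
    for i, votu in enumerate(counts.index):
        try:
            genewise[i] = _cr_profile_alpha(Y[i], X_full, offset)
        except Exception:
            genewise[i] = np.nan
    ok = np.isfinite(genewise)
    priors = [None] * len(counts)
    if moderate and ok.sum() >= 10:
        mu_bar = np.clip((Y / np.exp(offset)).mean(axis=1), 1e-8, None)
        trend = np.full(len(counts), np.nanmedian(genewise))
        trend[ok] = _dispersion_trend(mu_bar[ok], genewise[ok])
        log_res = np.log(np.clip(genewise[ok], 1e-8, None)) - np.log(trend[ok])
        sampling_var = float(polygamma(1, max(n - p_full, 1) / 2.0))
        prior_var = max(float(np.var(log_res)) - sampling_var, 0.25**2)
        priors = [
            (float(np.log(max(t, 1e-8))), prior_var) for t in trend
        ]

    rows = []
    for i, votu in enumerate(counts.index):
        y = Y[i]
        try:
            if priors[i] is not None:
                alpha = _cr_profile_alpha(y, X_full, offset, prior=priors[i])
            elif np.isfinite(genewise[i]):
                alpha = genewise[i]
            else:
                raise RuntimeError("dispersion estimation failed")
            full = _fit_nb(y, X_full, offset, alpha)
            red = _fit_nb(y, X_red, offset, alpha)
            lrt = max(0.0, 2.0 * (full.llf - red.llf))
            p = float(stats.chi2.sf(lrt, df))
        except Exception:
            logger.warning("NB fit failed for %s; assigning p=1", votu)
            alpha, lrt, p = np.nan, 0.0, 1.0
        rows.append((votu, lrt, df, p, alpha))
    table = pd.DataFrame(
        rows, columns=["votu_id", "lrt", "df", "p", "dispersion"]
    ).set_index("votu_id")
    table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    significant = list(table.index[table["padj"] < alpha_sig])
    return DAResult(table=table, significant=significant)


def depth_groups(
    significant: list[str],
    counts: pd.DataFrame,
    depth_levels,
    k: int = 3,
) -> dict[str, int]:
    """Group significant vOTUs by depth profile.

    Size-factor-normalized means per depth level are Z-transformed per
    vOTU (population standard deviation across levels; constant profiles
    become zero vectors), clustered by complete-linkage agglomeration on
    Euclidean distance and cut into ``k`` groups.  Groups are labeled
    1..k by the depth level of their peak mean Z (shallow to deep).
    """
    if not significant:
        return {}
    levels = pd.Series(list(depth_levels), index=counts.columns)
    order = list(dict.fromkeys(levels))
    sf = size_factors(counts)
    norm = counts.loc[significant].div(sf, axis=1)
    prof = pd.DataFrame(
        {lv: norm.loc[:, levels[levels == lv].index].mean(axis=1) for lv in order}
    )
    mean = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.info("%d constant-profile vOTU(s) assigned zero Z vectors", int(flat.sum()))
    z = prof.sub(mean, axis=0).div(sd.replace(0, 1), axis=0)
    if len(significant) == 1 or k == 1:
        raw = {v: 1 for v in significant}
    else:
        link = sch.linkage(z.to_numpy(), method="complete", metric="euclidean")
        cut = sch.fcluster(link, t=min(k, len(significant)), criterion="maxclust")
        raw = dict(zip(significant, cut))
    # relabel clusters by the depth of their peak mean Z
    peaks = {}
    for cl in set(raw.values()):
        members = [v for v, c in raw.items() if c == cl]
        peaks[cl] = int(np.argmax(z.loc[members].mean(axis=0).to_numpy()))
    ranked = sorted(peaks, key=lambda c: (peaks[c], c))
    relabel = {c: i + 1 for i, c in enumerate(ranked)}
    return {v: relabel[c] for v, c in raw.items()}


def trait_enrichment(
    group_sets: dict[int, set[str]], trait_set: set[str], universe: set[str]
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a trait in each group."""
    N = len(universe)
    K = len(trait_set & universe)
    out = []
    for gid in sorted(group_sets):
        members = group_sets[gid] & universe
        n = len(members)
        k = len(members & trait_set)
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        out.append(EnrichmentResult(gid, k, n, K, N, min(p, 1.0)))
    return out


def two_sample_t(x, y) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)
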