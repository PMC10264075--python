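"""Shape statistics: PCA, mixture-model clustering, allometry.

The dimorphism test follows the now-standard recipe for detecting
bimodality in a morphometric sample without a priori groups: project the
superimposed shapes onto principal components, fit univariate Gaussian
mixtures with 1..G_max components (equal-variance and free-variance
variants) to each axis by EM, and let BIC choose the component count.
An axis is flagged "dimorphic, size-independent" when the best model has
exactly two components *and* the axis scores show no significant Pearson
correlation with log centroid size — the latter guards against reading
ontogenetic or static allometry as dimorphism.

BIC here is the maximised convention, 2·loglik − k·log n (the model with
the *highest* BIC wins); users of the minimised convention should negate
the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry_core import GPAResult, gpa


# ---------------------------------------------------------------------------
# PCA of superimposed shapes
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal components of flattened aligned coordinates.

    ``scores`` is (n, k); ``loadings`` is (k, 3p) with orthonormal rows,
    each oriented so its largest-magnitude entry is positive;
    ``variance_fraction`` sums to 1 over the k = min(n−1, 3p) retained
    components.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    mean_flat: np.ndarray
    specimen_ids: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(gpa_result: GPAResult) -> PCAResult:
    """PCA of the superimposed sample (covariance eigendecomposition via
    SVD of the centered, flattened coordinates)."""
    n = gpa_result.n_specimens
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    X = np.stack([a.ravel() for a in gpa_result.aligned])
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, X.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|.| loading element positive
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = U * s * flip[None, :]
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return PCAResult(
        scores=scores,
        loadings=Vt,
        variance_fraction=frac,
        mean_flat=mean,
        specimen_ids=list(gpa_result.specimen_ids),
    )


# ---------------------------------------------------------------------------
# univariate Gaussian mixtures with BIC
# ---------------------------------------------------------------------------

@dataclass
class GMMResult:
    """BIC-selected univariate Gaussian mixture on one PC axis."""

    axis: int
    bic_table: dict  # {(variant, G): BIC}
    selected_G: int
    selected_model: str
    means: np.ndarray
    variances: np.ndarray
    mixing_proportions: np.ndarray
    assignments: np.ndarray
    posterior: np.ndarray
    loglik: float


def _em_1d(x, mu, var, pi, equal_variance, tol=1e-5, max_iter=200, track_history=False):
    """EM for 1D Gaussian mixtures, batched over R independent starts.

    *mu*, *var*, *pi* are (R, G).  Returns ``(mu, var, pi, loglik (R,),
    history)``: degenerate runs (emptied or collapsed components) carry
    ``loglik = -inf``.  Stopping uses Aitken acceleration of the
    per-iteration loglik, which is non-decreasing for every run (the
    optional *history* records it, NaN-padded after a run finishes).
    Converged runs are removed from the working batch as they finish.
    """
    x = np.asarray(x, float)
    n = len(x)
    var_floor = 1e-12 * max(np.var(x), np.finfo(float).tiny)
    mu, var, pi = (np.array(a, float, copy=True) for a in (mu, var, pi))
    R, G = mu.shape
    out_ll = np.full(R, -np.inf)
    idx = np.arange(R)  # global ids of still-iterating runs
    amu, avar, api = mu.copy(), var.copy(), pi.copy()
    aprev = np.full(R, -np.inf)
    aprev2 = np.full(R, -np.inf)
    history = [] if track_history else None
    for it in range(max_iter):
        with np.errstate(divide="ignore"):
            logp = (
                -0.5 * np.log(2 * np.pi * avar)[:, None, :]
                - 0.5 * (x[None, :, None] - amu[:, None, :]) ** 2 / avar[:, None, :]
                + np.log(api)[:, None, :]
            )
        m = logp.max(axis=2, keepdims=True)
        lse = m[..., 0] + np.log(np.sum(np.exp(logp - m), axis=2))
        ll = lse.sum(axis=1)
        if track_history:
            row = np.full(R, np.nan)
            row[idx] = ll
            history.append(row)
        # Aitken-accelerated stopping: project the asymptotic loglik
        # from the last three values; stop when the projected remaining
        # gain (or the raw increment) is below tolerance
        scale = tol * np.maximum(1.0, np.abs(ll))
        delta = ll - aprev
        with np.errstate(divide="ignore", invalid="ignore"):
            a = delta / (aprev - aprev2)
            gain = np.where((a > 0) & (a < 1), delta * a / (1.0 - a), np.inf)
        done = np.isfinite(aprev) & ((delta < scale) | (np.abs(gain) < scale))
        if it == max_iter - 1:
            done[:] = True
        if done.any():  # finalize: params are the ones ll was computed for
            gidx = idx[done]
            mu[gidx], var[gidx], pi[gidx] = amu[done], avar[done], api[done]
            out_ll[gidx] = ll[done]
        cont = ~done
        if not cont.any():
            break
        # M step for the continuing runs only
        resp = np.exp(logp[cont] - lse[cont][..., None])
        nk = resp.sum(axis=1)  # (A, G)
        emptied = (nk < 1e-10).any(axis=1)
        safe_nk = np.maximum(nk, 1e-300)
        pi_new = nk / n
        mu_new = np.einsum("rng,n->rg", resp, x) / safe_nk
        dev2 = (x[None, :, None] - mu_new[:, None, :]) ** 2
        if equal_variance:
            v = np.einsum("rng,rng->r", resp, dev2) / n
            var_new = np.repeat(np.maximum(v, var_floor)[:, None], G, axis=1)
            collapsed = (v <= var_floor) & (np.var(x) > 0)
        else:
            var_new = np.maximum(np.einsum("rng,rng->rg", resp, dev2) / safe_nk, var_floor)
            collapsed = (var_new <= var_floor).any(axis=1) & (np.var(x) > 0)
        bad = emptied | collapsed
        if bad.any():
            out_ll[idx[cont][bad]] = -np.inf  # degenerate: rejected
        keep = ~bad
        amu, avar, api = mu_new[keep], var_new[keep], pi_new[keep]
        aprev2 = aprev[cont][keep]
        aprev = ll[cont][keep]
        idx = idx[cont][keep]
        if len(idx) == 0:
            break
    history = np.asarray(history) if track_history else np.empty((0, R))
    return mu, var, pi, out_ll, history


def _posterior_1d(x, mu, var, pi):
    """Responsibilities of a fitted 1D mixture."""
    with np.errstate(divide="ignore"):
        logp = (
            -0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
            + np.log(pi)[None, :]
        )
    m = logp.max(axis=1, keepdims=True)
    p = np.exp(logp - m)
    return p / p.sum(axis=1, keepdims=True)


def _quantile_init(x, G):
    qs = (np.arange(G) + 0.5) / G
    mu = np.quantile(x, qs)
    v = max(np.var(x) / max(G, 1), 1e-10 * max(np.var(x), 1e-300))
    return mu, np.full(G, v), np.full(G, 1.0 / G)


def fit_gmm_1d(
    values,
    G_max: int = 9,
    axis: int = 1,
    seed: int = 0,
    n_restarts: int = 10,
) -> GMMResult:
    """Fit 1D Gaussian mixtures for G = 1..G_max, equal- and
    free-variance, and keep the (variant, G) pair with the highest BIC.

    Initialisation is deterministic: a quantile-based partition plus
    *n_restarts* seeded random starts per (variant, G); ties in BIC are
    broken toward smaller G, then toward the equal-variance variant.
    """
    x = np.asarray(values, float).ravel()
    n = len(x)
    if n < 5:
        raise ValueError("mixture fitting needs at least 5 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    # boundary cases: one or two distinct values admit only zero-variance
    # components (the mixture likelihood is unbounded), so the exact
    # partition is returned directly rather than via EM
    uniq = np.unique(x)
    if len(uniq) <= 2:
        warnings.warn(
            f"only {len(uniq)} distinct value(s): returning the exact "
            "zero-variance partition",
            stacklevel=2,
        )
        G = len(uniq)
        assign = np.searchsorted(uniq, x)
        post = np.zeros((n, G))
        post[np.arange(n), assign] = 1.0
        return GMMResult(
            axis=axis,
            bic_table={("equal_variance", G): np.inf},
            selected_G=G,
            selected_model="equal_variance",
            means=uniq.astype(float),
            variances=np.zeros(G),
            mixing_proportions=np.bincount(assign, minlength=G) / n,
            assignments=assign,
            posterior=post,
            loglik=np.inf,
        )
    rng = np.random.default_rng(seed)
    bic_table = {}
    best = None  # (bic, G, variant_rank, fit)
    for G in range(1, G_max + 1):
        for variant in ("equal_variance", "variable_variance"):
            equal = variant == "equal_variance"
            k = 2 * G if equal else 3 * G - 1  # means + variance(s) + mixing
            starts = [_quantile_init(x, G)]
            for _ in range(n_restarts):
                mu = rng.choice(x, size=G, replace=False) if G <= n else rng.choice(x, size=G)
                mu = mu + rng.normal(0, np.std(x) * 1e-3, G)
                starts.append((mu, np.full(G, np.var(x) / G + 1e-12), np.full(G, 1.0 / G)))
            mu0 = np.stack([s[0] for s in starts])
            var0 = np.stack([s[1] for s in starts])
            pi0 = np.stack([s[2] for s in starts])
            mu_f, var_f, pi_f, ll, _ = _em_1d(x, mu0, var0, pi0, equal)
            r_best = int(np.argmax(ll))
            if not np.isfinite(ll[r_best]):
                bic_table[(variant, G)] = -np.inf
                continue
            fit = (mu_f[r_best], var_f[r_best], pi_f[r_best], float(ll[r_best]))
            bic = 2 * fit[3] - k * np.log(n)
            bic_table[(variant, G)] = bic
            rank = 0 if equal else 1
            if best is None or (bic, -G, -rank) > (best[0], -best[1], -best[2]):
                best = (bic, G, rank, fit)
    if best is None:
        raise RuntimeError("no mixture model could be fitted")
    _, G, rank, (mu, var, pi, loglik) = best
    order = np.argsort(mu)
    mu, var, pi = mu[order], var[order], pi[order]
    resp = _posterior_1d(x, mu, var, pi)
    return GMMResult(
        axis=axis,
        bic_table=bic_table,
        selected_G=G,
        selected_model="equal_variance" if rank == 0 else "variable_variance",
        means=mu,
        variances=var,
        mixing_proportions=pi,
        assignments=np.argmax(resp, axis=1),
        posterior=resp,
        loglik=loglik,
    )


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryResult:
    """Pearson correlation between axis scores and log centroid size."""

    axis: int
    r: float
    p_value: float
    n: int


def allometry_test(scores, log_cs, axis: int = 1) -> AllometryResult:
    """Two-sided Pearson test of scores against log centroid size."""
    scores = np.asarray(scores, float).ravel()
    log_cs = np.asarray(log_cs, float).ravel()
    if len(scores) != len(log_cs):
        raise ValueError("scores and sizes differ in length")
    if len(scores) < 3:
        raise ValueError("allometry test needs at least 3 specimens")
    if np.var(scores) == 0 or np.var(log_cs) == 0:
        raise ValueError("degenerate variance: constant scores or sizes")
    r, p = stats.pearsonr(scores, log_cs)
    return AllometryResult(axis=axis, r=float(r), p_value=float(p), n=len(scores))


# ---------------------------------------------------------------------------
# dimorphism scan
# ---------------------------------------------------------------------------

@dataclass
class AxisScan:
    gmm: GMMResult
    allometry: AllometryResult
    flagged: bool


def default_scan_axes(pca_result: PCAResult, min_fraction: float = 0.10, max_axes: int = 5):
    """Axes worth scanning: the leading PCs each explaining at least
    *min_fraction* of total variance (PC1 always included), capped at
    *max_axes*.  One-based."""
    axes = [1]
    for j in range(1, min(max_axes, pca_result.n_components)):
        if pca_result.variance_fraction[j] >= min_fraction:
            axes.append(j + 1)
        else:
            break
    return axes


def dimorphism_scan(
    pca_result: PCAResult,
    gpa_result: GPAResult,
    axes=None,
    G_max: int = 9,
    allometry_alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Per-axis mixture model + allometry test.

    Returns ``{axis (1-based): AxisScan}``; an axis is flagged dimorphic
    and size-independent when its selected G equals 2 and the allometry
    p-value exceeds *allometry_alpha*.
    """
    if axes is None:
        axes = default_scan_axes(pca_result)
    log_cs = gpa_result.log_centroid_sizes
    out = {}
    for ax in axes:
        if not 1 <= ax <= pca_result.n_components:
            raise ValueError(f"axis {ax} out of range (1..{pca_result.n_components})")
        scores = pca_result.scores[:, ax - 1]
        gmm = fit_gmm_1d(scores, G_max=G_max, axis=ax, seed=seed)
        allo = allometry_test(scores, log_cs, axis=ax)
        out[ax] = AxisScan(
            gmm=gmm,
            allometry=allo,
            flagged=(gmm.selected_G == 2 and allo.p_value > allometry_alpha),
        )
    return out


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

def repeatability_experiment(
    specimens,
    n_rep: int = 10,
    operator_noise: float = 1.0,
    seed: int = 0,
) -> dict:
    """Operator-error protocol: re-digitise three morphologically close
    specimens *n_rep* times each (noise stands in for the operator),
    superimpose and project the 3·n_rep configurations, and report

    ``separation`` = (minimum between-specimen distance) /
    (maximum within-specimen distance) in the PC1–PC2 plane.

    ``separation > 1`` means every replicate cloud is grouped and
    isolated, i.e. biological differences exceed operator error.
    """
    specimens = list(specimens)
    if len(specimens) != 3:
        raise ValueError("repeatability protocol expects exactly 3 base specimens")
    if operator_noise <= 0:
        raise ValueError("operator_noise must be positive")
    rng = np.random.default_rng(seed)
    configs, labels = [], []
    for s_idx, base in enumerate(specimens):
        for r in range(n_rep):
            noisy = base.points + rng.normal(0.0, operator_noise, base.points.shape)
            configs.append(base.with_points(noisy, specimen_id=f"{base.specimen_id}_rep{r}"))
            labels.append(s_idx)
    g = gpa(configs)
    p = pca(g)
    xy = p.scores[:, :2]
    labels = np.asarray(labels)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within_max = d[iu][same[iu]].max()
    between_min = d[iu][~same[iu]].min()
    separation = float(between_min / within_max) if within_max > 0 else np.inf
    if separation <= 1:
        warnings.warn(
            "replicate clouds overlap (separation <= 1): specimen differences "
            "are not resolvable above operator noise",
            stacklevel=2,
        )
    return {"configs": configs, "labels": labels, "pca": p, "gpa": g, "separation": separation}


# ---------------------------------------------------------------------------
# cluster consistency across analyses
# ---------------------------------------------------------------------------

def cluster_consistency(assign_a: dict, assign_b: dict) -> dict:
    """Agreement between two binary cluster assignments on shared ids.

    ``n_consistent`` is the maximum agreement over the two possible
    label bijections, so it is invariant to global label swaps.
    """
    shared = sorted(set(assign_a) & set(assign_b))
    if not shared:
        raise ValueError("no shared specimen ids between the two assignments")
    a = np.array([assign_a[i] for i in shared])
    b = np.array([assign_b[i] for i in shared])
    for arr, name in ((a, "first"), (b, "second")):
        if len(np.unique(arr)) > 2:
            raise ValueError(f"{name} assignment is not binary")
    agree = int(np.sum(a == b))
    return {"n_shared": len(shared), "n_consistent": max(agree, len(shared) - agree)}


def label_accuracy(pred, truth) -> float:
    """Fraction of correctly assigned binary labels after the optimal
    label bijection (chance level 0.5)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    agree = np.mean(pred == truth)
    return float(max(agree, 1 - agree))
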