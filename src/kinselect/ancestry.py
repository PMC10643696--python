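"""Admixture-model estimation of individual ancestry.

Model: genotype g_il ~ Binomial(2, p_il) with p_il = Σ_k q_ik f_kl, where
q_ik are per-individual ancestry fractions over K clusters (rows on the
simplex) and f_kl are per-cluster alternate-allele frequencies.  Parameters
are estimated by plain EM (responsibilities for alternate and reference
allele copies), with multiple seeded restarts keeping the best final
log-likelihood.  The log-likelihood omits the constant binomial
coefficient; it is non-decreasing at every EM iteration.

K is chosen by cross-validation: random folds of observed genotype entries
are masked, the model is refit, and masked entries are scored by mean
binomial deviance of the predicted dosage 2·p̂_il.

Cluster labels are arbitrary (label switching); ``align_clusters`` maps
clusters to reference subpopulation labels, after which ``classify_purity``
grades each individual as purebred, low_admixture or admixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import MISSING, validate_genotypes

logger = logging.getLogger(__name__)

EPS = 1e-6


@dataclass
class AncestryFit:
    K: int
    Q: np.ndarray
    F: np.ndarray
    loglik: float
    n_iter: int
    seed: int
    loglik_trace: np.ndarray = field(repr=False, default=None)
    cv_error: float | None = None


def _loglik(g: np.ndarray, obs: np.ndarray, P: np.ndarray) -> float:
    P = np.clip(P, 1e-12, 1 - 1e-12)
    ll = np.where(obs, g * np.log(P) + (2 - g) * np.log1p(-P), 0.0)
    return float(ll.sum())


class AdmixtureEM(BaseEstimator):
    """Unsupervised admixture fit (binomial mixture over K clusters).

    Parameters
    ----------
    n_clusters : K >= 1.
    tol : stop when the log-likelihood improves by less than this.
    max_iter : EM iteration cap per restart.
    n_restarts : seeded random initializations; best final loglik kept.
    random_state : master seed for all restarts.

    Fitted attributes: ``Q_`` (n x K), ``F_`` (K x L), ``loglik_``,
    ``n_iter_``, ``loglik_trace_`` (of the winning restart), ``seeds_``.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        tol: float = 1e-4,
        max_iter: int = 1000,
        n_restarts: int = 5,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        g = validate_genotypes(X)
        n, L = g.shape
        K = self.n_clusters
        if K < 1:
            raise ValueError("n_clusters must be >= 1")
        if K > n:
            raise ValueError(f"n_clusters={K} exceeds sample count {n}")
        obs = g != MISSING
        gf = np.where(obs, g, 0).astype(np.float64)

        ss = np.random.SeedSequence(self.random_state)
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(self.n_restarts)]
        best = None
        for seed in child_seeds:
            fit = self._fit_once(gf, obs, K, seed)
            if best is None or fit.loglik > best.loglik:
                best = fit
        self.Q_, self.F_ = best.Q, best.F
        self.loglik_ = best.loglik
        self.n_iter_ = best.n_iter
        self.loglik_trace_ = best.loglik_trace
        self.seeds_ = child_seeds
        self.seed_ = best.seed
        return self

    def _fit_once(self, gf, obs, K, seed) -> AncestryFit:
        rng = np.random.default_rng(seed)
        n, L = gf.shape
        Q = rng.dirichlet(np.ones(K), size=n)
        # init cluster frequencies as perturbed pooled frequencies
        n_l = obs.sum(axis=0)
        pooled = np.where(n_l > 0, gf.sum(axis=0) / np.maximum(2 * n_l, 1), 0.5)
        F = np.clip(pooled + rng.normal(0, 0.1, size=(K, L)), EPS, 1 - EPS)
        Q = np.clip(Q, EPS, 1 - EPS)
        Q /= Q.sum(axis=1, keepdims=True)

        L_i = obs.sum(axis=1).astype(np.float64)
        trace = []
        prev = -np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
            ll = _loglik(gf, obs, P)
            if not np.isfinite(ll):
                raise FloatingPointError(f"non-finite log-likelihood at iteration {n_iter}")
            trace.append(ll)
            if ll - prev < self.tol and n_iter > 1:
                break
            prev = ll
            num_q = np.empty_like(Q)
            f_num = np.empty_like(F)
            f_den = np.empty_like(F)
            ga = np.where(obs, gf, 0.0)
            gb = np.where(obs, 2.0 - gf, 0.0)
            for k in range(K):
                A = Q[:, k : k + 1] * F[k] / P
                B = Q[:, k : k + 1] * (1.0 - F[k]) / (1.0 - P)
                ta = ga * A
                tb = gb * B
                num_q[:, k] = (ta + tb).sum(axis=1)
                f_num[k] = ta.sum(axis=0)
                f_den[k] = f_num[k] + tb.sum(axis=0)
            Q = num_q / (2.0 * L_i)[:, None]
            with np.errstate(invalid="ignore", divide="ignore"):
                F_new = np.where(f_den > 0, f_num / np.maximum(f_den, 1e-300), F)
            F = np.clip(F_new, EPS, 1 - EPS)
            Q = np.clip(Q, EPS, 1 - EPS)
            Q /= Q.sum(axis=1, keepdims=True)
        final = _loglik(gf, obs, np.clip(Q @ F, 1e-12, 1 - 1e-12))
        trace.append(final)
        return AncestryFit(K, Q, F, final, n_iter, seed, np.asarray(trace))

    def predict_dosage(self, X=None) -> np.ndarray:
        """Expected genotype 2·p̂_il under the fitted model."""
        return 2.0 * np.clip(self.Q_ @ self.F_, 1e-12, 1 - 1e-12)


def admixture_fit(
    genotypes: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> AncestryFit:
    """Fit the admixture model; returns an :class:`AncestryFit`."""
    est = AdmixtureEM(K, tol, max_iter, n_restarts, seed).fit(genotypes)
    return AncestryFit(K, est.Q_, est.F_, est.loglik_, est.n_iter_, est.seed_, est.loglik_trace_)


def _deviance(g: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Binomial deviance per entry for genotypes in {0,1,2} vs predicted
    dosage in (0,2)."""
    p = np.clip(dosage / 2.0, 1e-12, 1 - 1e-12)
    g = np.asarray(g, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(g > 0, g * np.log(g / (2 * p)), 0.0)
        t2 = np.where(g < 2, (2 - g) * np.log((2 - g) / (2 - 2 * p)), 0.0)
    return 2.0 * (t1 + t2)


def cv_error(
    genotypes: np.ndarray,
    K: int,
    folds: int = 3,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
    n_restarts: int = 2,
) -> float:
    """Entry-masking cross-validation error for one K.

    Observed entries are randomly partitioned into ``folds`` folds; each
    fold is masked in turn, the model refit on the rest, and masked entries
    scored by binomial deviance of the predicted dosage.  Deterministic
    given the seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    g = validate_genotypes(genotypes).copy()
    obs_idx = np.argwhere(g != MISSING)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(obs_idx))
    fold_errors = []
    for f in range(folds):
        mask_idx = obs_idx[perm[f::folds]]
        g_train = g.copy()
        g_train[mask_idx[:, 0], mask_idx[:, 1]] = MISSING
        col_obs = (g_train != MISSING).sum(axis=0)
        usable = col_obs[mask_idx[:, 1]] > 0
        if not usable.all():
            logger.warning(
                "cv_error: fold %d left %d variant entries with no training "
                "observations; skipped",
                f,
                int((~usable).sum()),
            )
            mask_idx = mask_idx[usable]
        fit_seed = int(rng.integers(2**31))
        est = AdmixtureEM(K, tol, max_iter, n_restarts, fit_seed).fit(g_train)
        dosage = est.predict_dosage()
        dev = _deviance(
            g[mask_idx[:, 0], mask_idx[:, 1]], dosage[mask_idx[:, 0], mask_idx[:, 1]]
        )
        fold_errors.append(float(dev.mean()))
    return float(np.mean(fold_errors))


def choose_k(
    genotypes: np.ndarray, k_values, folds: int = 3, seed: int = 0, **kwargs
) -> pd.DataFrame:
    """CV error for each K in ``k_values``; lowest error is the chosen K."""
    rows = [
        {"K": int(k), "cv_error": cv_error(genotypes, int(k), folds, seed + int(k), **kwargs)}
        for k in k_values
    ]
    return pd.DataFrame(rows)


def align_clusters(Q: np.ndarray, labels) -> dict[int, str]:
    """Greedy cluster -> reference-label mapping.

    Repeatedly assigns the (label, cluster) pair with the largest mean
    ancestry fraction among that label's samples; ties resolve in label
    sort order.  Bijective when K equals the number of labels.
    """
    Q = np.asarray(Q, dtype=np.float64)
    labels = pd.Series(list(labels))
    uniq = sorted(labels.unique())
    means = np.vstack([Q[(labels == lab).to_numpy()].mean(axis=0) for lab in uniq])
    mapping: dict[int, str] = {}
    free_labels = list(range(len(uniq)))
    free_clusters = list(range(Q.shape[1]))
    while free_labels and free_clusters:
        sub = means[np.ix_(free_labels, free_clusters)]
        li, ci = np.unravel_index(np.argmax(sub), sub.shape)
        ties = np.argwhere(sub == sub[li, ci])
        if len(ties) > 1:
            logger.warning("align_clusters: tie resolved by label sort order")
            li, ci = ties[0]
        mapping[free_clusters[ci]] = uniq[free_labels[li]]
        free_labels.pop(li)
        free_clusters.pop(ci)
    return mapping


def classify_purity(
    q_row: np.ndarray, purity_tol: float = 0.001, admix_flag: float = 0.40
) -> tuple[int, float, str]:
    """Grade one individual's ancestry row.

    purebred when the dominant fraction is >= 1 − purity_tol (the numeric
    reading of "100% ancestry"); admixed when any non-dominant fraction
    exceeds ``admix_flag``; otherwise low_admixture.

    Returns (dominant_cluster, dominant_fraction, purity_class).
    """
    q = np.asarray(q_row, dtype=np.float64)
    if abs(q.sum() - 1.0) > 1e-6:
        raise ValueError(f"ancestry row does not sum to 1: {q.sum()}")
    k = int(np.argmax(q))
    dom = float(q[k])
    others = np.delete(q, k)
    if dom >= 1.0 - purity_tol:
        cls = "purebred"
    elif others.size and others.max() > admix_flag:
        cls = "admixed"
    else:
        cls = "low_admixture"
    return k, dom, cls


def purity_calls(
    Q: np.ndarray,
    sample_ids,
    cluster_labels: dict[int, str] | None = None,
    purity_tol: float = 0.001,
    admix_flag: float = 0.40,
) -> pd.DataFrame:
    """Per-sample purity table from a Q matrix."""
    rows = []
    for sid, q in zip(sample_ids, np.asarray(Q)):
        k, dom, cls = classify_purity(q, purity_tol, admix_flag)
        rows.append(
            {
                "sample_id": sid,
                "dominant_cluster": cluster_labels.get(k, str(k)) if cluster_labels else str(k),
                "dominant_fraction": dom,
                "purity_class": cls,
            }
        )
    return pd.DataFrame(rows)
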