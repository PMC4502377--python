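"""Bayesian admixture inference with replicate alignment and model choice.

The model is the classic admixture model with independent allele
frequencies: individual i draws each of its two allele copies at locus l
from ancestral population k with probability Q[i, k], and population k
carries the alternative allele at frequency P[k, l]. Inference is by Gibbs
sampling over the latent population-of-origin indicators with conjugate
updates — P | Z from a Beta posterior under a uniform prior and Q | Z from a
Dirichlet(alpha + counts) posterior — returning posterior-mean point
estimates over the post-burn-in sweeps.

Replicate runs are aligned by exhaustive search over column permutations
(label switching), summarised by the mean pairwise similarity H' of aligned
Q matrices, and the number of populations is chosen by the second-order
rate of change of the log-likelihood across K (the Evanno delta-K
statistic). Samples are finally assigned to a population when their
ancestry proportion reaches a purity threshold, and labelled Mixed
otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .matrix import MISSING, GenotypeMatrix

MIXED = "Mixed"


def _as_dosage(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.dosage
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x loci dosage matrix")
    return X


def _multinomial_counts_le2(rng, n, weights, total):
    """Assign n <= 2 copies per cell to K bins with probability weights/total.

    Stick-breaking over bins: each step draws a binomial, exact for n <= 2
    via two Bernoulli variates, fully vectorised. Returns a (K, N, L)
    integer count array.
    """
    K = weights.shape[2]
    counts = np.zeros((K,) + n.shape, dtype=np.int64)
    if K == 1:
        counts[0] = n
        return counts
    u = rng.random((K - 1, 2) + n.shape)
    remaining = n
    mass_left = total.copy()
    for k in range(K - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = weights[..., k] / mass_left
        p = np.nan_to_num(p, nan=0.0, posinf=0.0, neginf=0.0)
        c = ((u[k, 0] < p) & (remaining >= 1)).astype(np.int64)
        c += ((u[k, 1] < p) & (remaining == 2)).astype(np.int64)
        counts[k] = c
        remaining = remaining - c
        mass_left -= weights[..., k]
    counts[K - 1] = remaining
    return counts


@dataclass
class AdmixtureRun:
    """Point estimates and trace of one admixture fit."""

    Q: np.ndarray  # (N, K) posterior-mean ancestry proportions
    P: np.ndarray  # (K, L) posterior-mean alt-allele frequencies
    loglik_trace: np.ndarray  # length burn_in + n_reps
    K: int
    burn_in: int
    n_reps: int
    seed: object = None

    @property
    def mean_loglik(self) -> float:
        """Mean log-likelihood over post-burn-in sweeps (the Evanno L(K))."""
        return float(self.loglik_trace[self.burn_in:].mean())


class AdmixtureModel(BaseEstimator):
    """Gibbs-sampled admixture model (scikit-learn estimator interface).

    Parameters
    ----------
    n_populations : int
        Number of ancestral populations K.
    burn_in, n_reps : int
        Discarded and retained Gibbs sweeps. The survey default
        (5000 / 25000) suits final analyses; recovery tests use a
        reduced chain.
    alpha : float
        Symmetric Dirichlet prior on ancestry proportions.
    random_state : int, Generator or SeedSequence, optional

    Attributes
    ----------
    Q_ : ndarray of shape (n_samples, K)
        Posterior-mean ancestry proportions; rows sum to 1.
    P_ : ndarray of shape (K, n_loci)
        Posterior-mean population alternative-allele frequencies.
    loglik_trace_ : ndarray of shape (burn_in + n_reps,)
        Log-likelihood at every sweep.
    """

    def __init__(
        self,
        n_populations: int = 2,
        burn_in: int = 5000,
        n_reps: int = 25000,
        alpha: float = 1.0,
        random_state=None,
    ):
        self.n_populations = n_populations
        self.burn_in = burn_in
        self.n_reps = n_reps
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y=None):
        """Run the Gibbs sampler on a dosage matrix (or GenotypeMatrix).

        Missing dosages (coded -1) contribute no allele copies to the
        likelihood or the conditional updates.
        """
        dosage = _as_dosage(X)
        K = self.n_populations
        N, L = dosage.shape
        if K < 1:
            raise ValueError("n_populations must be >= 1")
        if K > N:
            raise ValueError(f"n_populations={K} exceeds n_samples={N}")
        if L < 1:
            raise ValueError("matrix has no loci")
        rng = np.random.default_rng(self.random_state)

        called = dosage != MISSING
        n_alt = np.where(called, dosage, 0).astype(np.int64)
        n_ref = np.where(called, 2 - dosage, 0).astype(np.int64)

        Q = rng.dirichlet(np.full(K, self.alpha), size=N)
        P = rng.uniform(size=(K, L))
        sum_q = np.zeros((N, K))
        sum_p = np.zeros((K, L))
        n_iter = self.burn_in + self.n_reps
        trace = np.empty(n_iter)

        for t in range(n_iter):
            w_alt = Q[:, None, :] * P.T[None, :, :]  # (N, L, K)
            w_ref = Q[:, None, :] - w_alt  # Q * (1 - P)
            s_alt = w_alt.sum(axis=2)
            s_ref = 1.0 - s_alt  # ancestry proportions sum to 1
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = float(
                    (n_alt * np.log(s_alt) + n_ref * np.log(s_ref))[called].sum()
                )
            if not math.isfinite(ll):
                raise RuntimeError(f"non-finite log-likelihood at iteration {t}")
            trace[t] = ll

            c_alt = _multinomial_counts_le2(rng, n_alt, w_alt, s_alt)
            c_ref = _multinomial_counts_le2(rng, n_ref, w_ref, s_ref)

            P = rng.beta(1.0 + c_alt.sum(axis=1), 1.0 + c_ref.sum(axis=1))
            np.clip(P, 1e-12, 1.0 - 1e-12, out=P)
            n_ik = (c_alt + c_ref).sum(axis=2).T  # (N, K)
            gam = rng.standard_gamma(self.alpha + n_ik)
            Q = gam / gam.sum(axis=1, keepdims=True)

            if t >= self.burn_in:
                sum_q += Q
                sum_p += P

        self.Q_ = sum_q / self.n_reps
        self.P_ = sum_p / self.n_reps
        self.loglik_trace_ = trace
        self.n_features_in_ = L
        return self

    def fit_predict(self, X, y=None, threshold: float = 0.75):
        """Fit, then assign each sample by the purity threshold."""
        self.fit(X)
        return assign_populations(self.Q_, threshold=threshold)["label"].to_numpy()

    def score(self, X=None, y=None) -> float:
        check_is_fitted(self, "loglik_trace_")
        return float(self.loglik_trace_[self.burn_in:].mean())


def fit_admixture(
    gm, K: int, burn_in: int = 5000, n_reps: int = 25000, seed=None
) -> AdmixtureRun:
    """Functional wrapper over :class:`AdmixtureModel`."""
    model = AdmixtureModel(
        n_populations=K, burn_in=burn_in, n_reps=n_reps, random_state=seed
    ).fit(gm)
    return AdmixtureRun(
        Q=model.Q_, P=model.P_, loglik_trace=model.loglik_trace_,
        K=K, burn_in=burn_in, n_reps=n_reps, seed=seed,
    )


def replicate_seed(master_seed: int, K: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-run stream: replicate r of K k from one master seed."""
    return np.random.SeedSequence(master_seed, spawn_key=(K, replicate))


def run_replicates(
    gm, k_values, n_replicates: int, burn_in: int, n_reps: int, seed: int
) -> dict[int, list[AdmixtureRun]]:
    """Fit ``n_replicates`` independent chains for every K in ``k_values``."""
    runs: dict[int, list[AdmixtureRun]] = {}
    for K in k_values:
        runs[K] = [
            fit_admixture(gm, K, burn_in, n_reps, seed=replicate_seed(seed, K, r))
            for r in range(n_replicates)
        ]
    return runs


# -- replicate alignment (label switching) ----------------------------------


def similarity(q_a: np.ndarray, q_b: np.ndarray) -> float:
    """G statistic: 1 - ||Qa - Qb||_F / sqrt(2N), in [0, 1]."""
    n = q_a.shape[0]
    return 1.0 - float(np.linalg.norm(q_a - q_b)) / math.sqrt(2.0 * n)


@dataclass
class RunAlignment:
    """Column permutations aligning replicate runs to the first run."""

    permutations: list[tuple[int, ...]]
    pairwise_g: np.ndarray  # (R, R) similarity after alignment
    h_prime: float
    consensus_q: np.ndarray
    single_run: bool = False


def align_runs(runs) -> RunAlignment:
    """Align replicate Q matrices by exhaustive column permutation.

    Each run's columns are permuted to maximise similarity with the first
    run (exact for the K! search space, feasible for K <= 8); H' is the
    mean pairwise similarity of the aligned matrices and the consensus Q
    is their cell-wise mean. A single run yields H' = 1.0, flagged.
    """
    qs = [r.Q if isinstance(r, AdmixtureRun) else np.asarray(r) for r in runs]
    if not qs:
        raise ValueError("no runs to align")
    n, k = qs[0].shape
    for q in qs[1:]:
        if q.shape != (n, k):
            raise ValueError(f"run shape {q.shape} does not match ({n}, {k})")
    if k > 8:
        warnings.warn(f"exhaustive alignment over {k}! permutations; this may be slow")

    perms: list[tuple[int, ...]] = [tuple(range(k))]
    aligned = [qs[0]]
    for q in qs[1:]:
        best, best_g = None, -np.inf
        for perm in itertools.permutations(range(k)):
            g = similarity(qs[0], q[:, perm])
            if g > best_g:
                best, best_g = perm, g
        perms.append(best)
        aligned.append(q[:, best])

    r = len(aligned)
    pairwise = np.ones((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            pairwise[i, j] = pairwise[j, i] = similarity(aligned[i], aligned[j])
    if r == 1:
        h_prime, single = 1.0, True
    else:
        iu = np.triu_indices(r, k=1)
        h_prime, single = float(pairwise[iu].mean()), False
    consensus = np.mean(aligned, axis=0)
    return RunAlignment(perms, pairwise, h_prime, consensus, single_run=single)


# -- Evanno delta-K ----------------------------------------------------------


@dataclass
class EvannoTable:
    table: pd.DataFrame
    best_k: int | None = None


def evanno_delta_k(loglik_by_k: dict) -> EvannoTable:
    """Evanno second-order rate-of-change statistic across K.

    Parameters
    ----------
    loglik_by_k
        Mapping K -> replicate mean log-likelihoods (floats) or
        :class:`AdmixtureRun` objects. Requires at least three consecutive
        K values with >= 2 replicates each.

    Notes
    -----
    With L(K) the replicate mean and s(K) the replicate standard deviation,
    L'(K) = L(K) - L(K-1), L''(K) = |L'(K+1) - L'(K)| and
    delta-K = L''(K) / s(K), defined for interior K only. A replicate
    standard deviation of zero yields +inf with a warning.
    """
    ks = sorted(loglik_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    vals = {}
    for k in ks:
        reps = [
            r.mean_loglik if isinstance(r, AdmixtureRun) else float(r)
            for r in loglik_by_k[k]
        ]
        if len(reps) < 2:
            raise ValueError(f"need >= 2 replicates at K={k}")
        vals[k] = np.asarray(reps, dtype=float)

    rows = []
    for k in ks:
        mean = vals[k].mean()
        sd = vals[k].std(ddof=1)
        lp = mean - vals[k - 1].mean() if k - 1 in vals else np.nan
        lpp = np.nan
        if k - 1 in vals and k + 1 in vals:
            lp_next = vals[k + 1].mean() - mean
            lpp = abs(lp_next - lp)
        if np.isnan(lpp):
            delta = np.nan
        elif sd == 0.0:
            warnings.warn(f"zero replicate s.d. at K={k}; delta-K is +inf")
            delta = np.inf
        else:
            delta = lpp / sd
        rows.append(
            {"K": k, "n_reps": len(vals[k]), "mean_lnL": mean, "sd_lnL": sd,
             "L_prime": lp, "L_double_prime": lpp, "delta_K": delta}
        )
    table = pd.DataFrame(rows)
    defined = table["delta_K"].notna()
    best = int(table.loc[defined, "delta_K"].idxmax()) if defined.any() else None
    best_k = int(table.loc[best, "K"]) if best is not None else None
    return EvannoTable(table=table, best_k=best_k)


# -- purity assignment -------------------------------------------------------


def assign_populations(
    consensus_q: np.ndarray,
    threshold: float = 0.75,
    samples: list[str] | None = None,
    population_names: list[str] | None = None,
) -> pd.DataFrame:
    """Label each sample pop_k when Q[i, k] >= threshold, else Mixed.

    The threshold is inclusive ("at least"); it must exceed 0.5 so that at
    most one population can qualify.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    q = np.asarray(consensus_q, dtype=float)
    n, k = q.shape
    names = population_names or [f"pop_{i + 1}" for i in range(k)]
    best = q.argmax(axis=1)
    labels = [
        names[best[i]] if q[i, best[i]] >= threshold else MIXED for i in range(n)
    ]
    return pd.DataFrame(
        {
            "sample": samples if samples is not None else list(range(n)),
            "label": labels,
            "max_q": q.max(axis=1),
            **{names[j]: q[:, j] for j in range(k)},
        }
    )
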