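"""Eye-movement analysis with hidden Markov models (EMHMM).

Three pieces:

* :class:`VariationalGaussianHMM` fits an HMM with Gaussian emissions
  to fixation sequences by variational Bayes (Dirichlet priors on the
  initial/transition distributions, Normal--Wishart on the emissions).
  The number of ROIs is selected automatically: every state count in a
  preset range is fitted from many random restarts and the model with
  the highest variational lower bound is kept; states that end up with
  negligible occupancy are pruned.

* :class:`HMMClusterer` groups individual HMMs into a small number of
  representative patterns.  It uses the virtual-sample approximation
  to hierarchical EM: each input HMM is represented by sequences
  sampled from it, cluster representatives are HMMs refitted on their
  members' virtual samples, and individuals are (re)assigned to the
  representative that gives their samples the highest likelihood.  The
  representative state count follows the median rule (median of the
  inputs' state counts, halves rounded up).

* Likelihood scales and consistency: :func:`ab_scale` contrasts an
  individual's data log-likelihood under two representative patterns,
  (A - B) / (|A| + |B|); :func:`overall_entropy` measures eye-movement
  consistency as the joint entropy of a T-fixation sequence under the
  HMM — discrete state-sequence terms plus Gaussian differential
  entropy of the emissions, in nats.  Lower entropy means a more
  predictable, more consistent strategy.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "VariationalGaussianHMM",
    "HMMClusterer",
    "ClusterResult",
    "EntropyReport",
    "fit_vbhmm",
    "forward_loglik",
    "vhem_cluster",
    "ab_scale",
    "overall_entropy",
    "sample_hmm_sequences",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# parameter plumbing
# ---------------------------------------------------------------------------

def hmm_params(model, include_scale: bool = True) -> dict:
    """Normalise a model-ish object to {prior, transition, means, covariances}.

    Accepts a dict with those keys, a fitted VariationalGaussianHMM, or
    a GazeStrategy (whose saccade noise is folded into the emissions).
    """
    if isinstance(model, dict):
        return model
    if isinstance(model, VariationalGaussianHMM):
        return dict(
            prior=model.prior_,
            transition=model.transition_,
            means=model.means_,
            covariances=model.covariances_,
        )
    if hasattr(model, "effective_hmm"):
        return model.effective_hmm(include_scale=include_scale)
    raise TypeError(f"cannot interpret {type(model).__name__} as an HMM")


def _content_hash(params: dict) -> int:
    """Order-independent-of-caller, content-based 31-bit hash of HMM parameters."""
    buf = b"".join(
        np.ascontiguousarray(np.round(np.asarray(params[k], dtype=float), 6)).tobytes()
        for k in ("prior", "transition", "means", "covariances")
    )
    return zlib.crc32(buf) & 0x7FFFFFFF


def sample_hmm_sequences(params: dict, n_sequences: int, length: int, rng) -> np.ndarray:
    """Sample (n_sequences, length, d) observation sequences from an HMM."""
    params = hmm_params(params)
    pi, A = np.asarray(params["prior"]), np.asarray(params["transition"])
    means = np.asarray(params["means"])
    chols = [np.linalg.cholesky(c) for c in np.asarray(params["covariances"])]
    K, d = means.shape
    out = np.empty((n_sequences, length, d))
    for i in range(n_sequences):
        z = rng.choice(K, p=pi)
        for t in range(length):
            out[i, t] = means[z] + chols[z] @ rng.standard_normal(d)
            if t < length - 1:
                z = rng.choice(K, p=A[z])
    return out


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(x; mean, cov) for X of shape (..., d)."""
    d = mean.shape[0]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff[..., None])[..., 0]
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * _LOG2PI + logdet + (sol**2).sum(axis=-1))


def forward_loglik(model, sequence) -> float:
    """Exact log marginal likelihood of one sequence (forward algorithm).

    Uses the model's posterior-mean parameters and a log-sum-exp
    stabilised forward recursion.
    """
    params = hmm_params(model)
    X = np.asarray(sequence if isinstance(sequence, np.ndarray) else sequence.as_array())
    means = np.asarray(params["means"])
    covs = np.asarray(params["covariances"])
    K, d = means.shape
    if X.shape[-1] != d:
        raise ValueError(f"sequence dimension {X.shape[-1]} != emission dimension {d}")
    logb = np.stack([_gauss_logpdf(X, means[k], covs[k]) for k in range(K)], axis=-1)  # (T, K)
    with np.errstate(divide="ignore"):
        logpi = np.log(np.asarray(params["prior"]))
        logA = np.log(np.asarray(params["transition"]))
    la = logpi + logb[0]
    for t in range(1, X.shape[0]):
        la = logsumexp(la[:, None] + logA, axis=0) + logb[t]
    return float(logsumexp(la))


def mean_sequence_loglik(model, sequences) -> float:
    """Per-sequence mean forward log-likelihood (scale-free in trial count)."""
    seqs = sequences if isinstance(sequences, np.ndarray) else [np.asarray(s if isinstance(s, np.ndarray) else s.as_array()) for s in sequences]
    return float(np.mean([forward_loglik(model, s) for s in seqs]))


# ---------------------------------------------------------------------------
# variational Bayesian HMM
# ---------------------------------------------------------------------------

def _kl_dirichlet(a: np.ndarray, a0: np.ndarray) -> float:
    sa, sa0 = a.sum(), a0.sum()
    return float(
        gammaln(sa)
        - gammaln(sa0)
        - (gammaln(a) - gammaln(a0)).sum()
        + ((a - a0) * (digamma(a) - digamma(sa))).sum()
    )


def _log_wishart_B(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    return float(
        -0.5 * nu * logdet
        - 0.5 * nu * d * np.log(2.0)
        - 0.25 * d * (d - 1) * np.log(np.pi)
        - gammaln(0.5 * (nu - np.arange(d))).sum()
    )


def _e_logdet_lambda(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    return float(digamma(0.5 * (nu - np.arange(d))).sum() + d * np.log(2.0) + logdet)


def _kl_gauss_wishart(m, beta, W, nu, m0, beta0, W0, nu0) -> float:
    """KL( N(m,(beta L)^-1) W(W,nu) || N(m0,(beta0 L)^-1) W(W0,nu0) )."""
    d = W.shape[0]
    elogdet = _e_logdet_lambda(W, nu)
    dm = m - m0
    kl_normal = 0.5 * (
        d * np.log(beta / beta0)
        + d * (beta0 / beta - 1.0)
        + beta0 * nu * dm @ W @ dm
    )
    # E[Lambda] = nu W, hence the tr(W0^{-1} E[Lambda]) term below
    kl_wishart = (
        _log_wishart_B(W, nu)
        - _log_wishart_B(W0, nu0)
        + 0.5 * (nu - nu0) * elogdet
        + 0.5 * nu * np.trace(np.linalg.solve(W0, W))
        - 0.5 * nu * d
    )
    return float(kl_normal + kl_wishart)


@dataclasses.dataclass
class _VBState:
    alpha: np.ndarray  # Dirichlet counts, prior
    A_alpha: np.ndarray  # Dirichlet counts, transitions (rows)
    beta: np.ndarray
    m: np.ndarray  # (K, d)
    W: np.ndarray  # (K, d, d)
    nu: np.ndarray


class VariationalGaussianHMM:
    """VB-fitted Gaussian HMM with automatic ROI-count selection.

    Parameters largely follow the usual conjugate-prior setup: symmetric
    Dirichlet concentration ``alpha0`` on prior/transition rows, and a
    Normal--Wishart emission prior centred at ``mean_prior`` (the data
    mean when not given) with a broad covariance derived from the data
    scatter and ``nu0 = d + 1`` degrees of freedom.

    After :meth:`fit`, posterior-mean parameters are available as
    ``prior_``, ``transition_``, ``means_``, ``covariances_``; the
    selected state count as ``n_states_`` and the variational lower
    bound as ``lower_bound_``.
    """

    def __init__(
        self,
        n_states: int | None = None,
        k_range: tuple = (1, 6),
        n_restarts: int = 100,
        alpha0: float = 1.0,
        beta0: float = 1e-2,
        mean_prior=None,
        max_iter: int = 100,
        tol: float = 1e-6,
        prune_threshold: float = 1e-2,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.alpha0 = alpha0
        self.beta0 = beta0
        self.mean_prior = mean_prior
        self.max_iter = max_iter
        self.tol = tol
        self.prune_threshold = prune_threshold
        self.random_state = random_state

    # -- public API ------------------------------------------------------
    def fit(self, sequences) -> "VariationalGaussianHMM":
        seqs = [np.atleast_2d(np.asarray(s if isinstance(s, np.ndarray) else s.as_array(), dtype=float)) for s in sequences]
        if len(seqs) < 2:
            raise ValueError("need at least 2 sequences")
        X_all = np.concatenate(seqs, axis=0)
        d = X_all.shape[1]
        if np.max(X_all.std(axis=0)) < 1e-8:
            warnings.warn("degenerate fixation data (no variability); returning a single-ROI model")
            self.prior_ = np.array([1.0])
            self.transition_ = np.array([[1.0]])
            self.means_ = X_all.mean(axis=0)[None, :]
            self.covariances_ = np.eye(d)[None, :, :] * 1e-6
            self.n_states_ = 1
            self.lower_bound_ = float("nan")
            return self
        groups = {}
        for s in seqs:
            groups.setdefault(s.shape[0], []).append(s)
        stacked = {T: np.stack(v) for T, v in groups.items()}
        seed = 0 if self.random_state is None else int(self.random_state)
        ks = [self.n_states] if self.n_states else range(self.k_range[0], self.k_range[1] + 1)
        best = None
        for K in ks:
            for r in range(self.n_restarts):
                # seed each (K, restart) independently so increasing the
                # restart count strictly extends the search
                rng = np.random.default_rng(np.random.SeedSequence([seed, int(K), r]))
                state, elbo = self._vb_em(stacked, X_all, K, rng)
                if best is None or elbo > best[1]:
                    best = (state, elbo, K)
        state, elbo, K = best
        self._finalise(state, elbo, X_all)
        return self

    def score(self, sequence) -> float:
        return forward_loglik(self, sequence)

    def to_dict(self) -> dict:
        return dict(
            K=int(self.n_states_),
            prior=self.prior_.tolist(),
            transition=self.transition_.tolist(),
            emissions=[
                dict(mean=m.tolist(), cov=c.tolist())
                for m, c in zip(self.means_, self.covariances_)
            ],
            lower_bound=float(self.lower_bound_),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "VariationalGaussianHMM":
        self = cls(n_states=d["K"])
        self.prior_ = np.array(d["prior"], dtype=float)
        self.transition_ = np.array(d["transition"], dtype=float)
        self.means_ = np.array([e["mean"] for e in d["emissions"]], dtype=float)
        self.covariances_ = np.array([e["cov"] for e in d["emissions"]], dtype=float)
        self.n_states_ = int(d["K"])
        self.lower_bound_ = float(d["lower_bound"])
        return self

    # -- internals -------------------------------------------------------
    def _hyper(self, X_all: np.ndarray, K: int):
        d = X_all.shape[1]
        m0 = np.asarray(self.mean_prior, dtype=float) if self.mean_prior is not None else X_all.mean(axis=0)
        S0 = np.diag(np.maximum(X_all.var(axis=0), 1e-6))
        nu0 = d + 1.0
        W0 = np.linalg.inv(S0) / nu0  # so that E[Lambda] under the prior = S0^-1
        return m0, float(self.beta0), W0, nu0

    def _vb_em(self, stacked: dict, X_all: np.ndarray, K: int, rng) -> tuple:
        d = X_all.shape[1]
        m0, beta0, W0, nu0 = self._hyper(X_all, K)
        # init: posterior means at random data points, modest counts
        idx = rng.choice(X_all.shape[0], size=K, replace=False)
        state = _VBState(
            alpha=np.full(K, self.alpha0 + 1.0),
            A_alpha=np.full((K, K), self.alpha0 + 1.0),
            beta=np.full(K, beta0 + 1.0),
            m=X_all[idx].copy(),
            W=np.repeat(W0[None], K, axis=0),
            nu=np.full(K, nu0 + 1.0),
        )
        prev_elbo = -np.inf
        elbo = -np.inf
        for _ in range(self.max_iter):
            stats, loglik_tilde = self._e_step(stacked, state, d)
            self._m_step(state, stats, m0, beta0, W0, nu0)
            elbo = loglik_tilde - self._kl(state, m0, beta0, W0, nu0)
            if abs(elbo - prev_elbo) < self.tol * (1.0 + abs(elbo)):
                break
            prev_elbo = elbo
        return state, elbo

    def _e_step(self, stacked: dict, st: _VBState, d: int):
        K = st.alpha.shape[0]
        Elogpi = digamma(st.alpha) - digamma(st.alpha.sum())
        ElogA = digamma(st.A_alpha) - digamma(st.A_alpha.sum(axis=1, keepdims=True))
        pit, At = np.exp(Elogpi), np.exp(ElogA)
        elogdet = np.array([_e_logdet_lambda(st.W[k], st.nu[k]) for k in range(K)])
        gamma1 = np.zeros(K)
        xi_sum = np.zeros((K, K))
        Nk = np.zeros(K)
        xbar_sum = np.zeros((K, d))
        scatter = np.zeros((K, d, d))
        loglik = 0.0
        for T, X in stacked.items():  # X: (N, T, d)
            N = X.shape[0]
            logb = np.empty((N, T, K))
            for k in range(K):
                diff = X - st.m[k]
                quad = st.nu[k] * np.einsum("ntd,de,nte->nt", diff, st.W[k], diff) + d / st.beta[k]
                logb[:, :, k] = 0.5 * (elogdet[k] - d * _LOG2PI) - 0.5 * quad
            b = np.exp(logb - logb.max(axis=2, keepdims=True))
            scale_log = logb.max(axis=2)  # (N, T)
            # scaled forward
            alph = np.empty((N, T, K))
            c = np.empty((N, T))
            a0 = pit * b[:, 0]
            c[:, 0] = a0.sum(axis=1)
            alph[:, 0] = a0 / c[:, 0, None]
            for t in range(1, T):
                at = (alph[:, t - 1] @ At) * b[:, t]
                c[:, t] = at.sum(axis=1)
                alph[:, t] = at / c[:, t, None]
            # scaled backward
            bet = np.empty((N, T, K))
            bet[:, T - 1] = 1.0
            for t in range(T - 2, -1, -1):
                bet[:, t] = (b[:, t + 1] * bet[:, t + 1]) @ At.T / c[:, t + 1, None]
            gamma = alph * bet  # (N, T, K), rows sum to 1
            loglik += float(np.log(c).sum() + scale_log.sum())
            gamma1 += gamma[:, 0].sum(axis=0)
            for t in range(1, T):
                xi = (
                    alph[:, t - 1, :, None]
                    * At[None]
                    * (b[:, t] * bet[:, t])[:, None, :]
                    / c[:, t, None, None]
                )
                xi_sum += xi.sum(axis=0)
            g = gamma.reshape(-1, K)  # (N*T, K)
            Xf = X.reshape(-1, d)
            Nk += g.sum(axis=0)
            xbar_sum += g.T @ Xf
            scatter += np.einsum("nk,nd,ne->kde", g, Xf, Xf)
        return dict(gamma1=gamma1, xi=xi_sum, Nk=Nk, xsum=xbar_sum, scatter=scatter), loglik

    def _m_step(self, st: _VBState, stats: dict, m0, beta0, W0, nu0):
        K, d = st.m.shape
        eps = 1e-10
        Nk = stats["Nk"]
        st.alpha = self.alpha0 + stats["gamma1"]
        st.A_alpha = self.alpha0 + stats["xi"]
        xbar = stats["xsum"] / np.maximum(Nk, eps)[:, None]
        st.beta = beta0 + Nk
        st.m = (beta0 * m0 + stats["xsum"]) / st.beta[:, None]
        st.nu = nu0 + Nk
        W0inv = np.linalg.inv(W0)
        for k in range(K):
            Sk = stats["scatter"][k] - np.outer(stats["xsum"][k], xbar[k])
            dm = xbar[k] - m0
            Winv = W0inv + Sk + (beta0 * Nk[k] / (beta0 + Nk[k])) * np.outer(dm, dm)
            st.W[k] = np.linalg.inv(0.5 * (Winv + Winv.T))

    def _kl(self, st: _VBState, m0, beta0, W0, nu0) -> float:
        K = st.alpha.shape[0]
        a0 = np.full(K, self.alpha0)
        kl = _kl_dirichlet(st.alpha, a0)
        for j in range(K):
            kl += _kl_dirichlet(st.A_alpha[j], a0)
        for k in range(K):
            kl += _kl_gauss_wishart(st.m[k], st.beta[k], st.W[k], st.nu[k], m0, beta0, W0, nu0)
        return kl

    def _finalise(self, st: _VBState, elbo: float, X_all: np.ndarray):
        d = X_all.shape[1]
        occupancy = st.beta - self.beta0  # total responsibility per state
        keep = occupancy > self.prune_threshold
        if not np.any(keep):
            keep[np.argmax(occupancy)] = True
        idx = np.flatnonzero(keep)
        prior = st.alpha[idx]
        self.prior_ = prior / prior.sum()
        A = st.A_alpha[np.ix_(idx, idx)]
        self.transition_ = A / A.sum(axis=1, keepdims=True)
        self.means_ = st.m[idx].copy()
        covs = []
        for k in idx:
            covs.append(np.linalg.inv(st.nu[k] * st.W[k]))  # (E[Lambda])^-1
        self.covariances_ = np.array(covs)
        self.n_states_ = int(len(idx))
        self.lower_bound_ = float(elbo)


def fit_vbhmm(
    sequences,
    k_range: tuple = (1, 6),
    restarts: int = 100,
    rng_seed: int | None = None,
    **hyperparams,
) -> VariationalGaussianHMM:
    """Fit an HMM to fixation sequences, selecting the ROI count by VB.

    For every state count in ``k_range``, ``restarts`` random
    initialisations are run and the model with the highest variational
    lower bound across all of them is returned.
    """
    return VariationalGaussianHMM(
        k_range=k_range, n_restarts=restarts, random_state=rng_seed, **hyperparams
    ).fit(sequences)


# ---------------------------------------------------------------------------
# clustering of HMMs (virtual-sample hierarchical EM)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterResult:
    representatives: list  # per-cluster HMM parameter dicts
    assignment: np.ndarray  # (n,) cluster index per individual
    logliks: np.ndarray  # (n, n_clusters) mean per-sequence log-likelihood
    ab_scale: np.ndarray  # (n,), (A - B)/(|A| + |B|) with A = cluster 0
    objective: float

    @property
    def loglik_A(self) -> np.ndarray:
        return self.logliks[:, 0]

    @property
    def loglik_B(self) -> np.ndarray:
        return self.logliks[:, 1]


class HMMClusterer:
    """Cluster HMMs into representative patterns (virtual-sample VHEM).

    Each input HMM is summarised by ``n_virtual_samples`` sequences of
    length ``virtual_length`` sampled from it (seeded from the master
    seed and the HMM's own parameters, so results do not depend on
    input order).  Hard EM then alternates between refitting one
    representative HMM per cluster on its members' virtual samples and
    reassigning each HMM to the representative under which its samples
    are most likely.  The best of ``n_restarts`` initialisations by
    total data log-likelihood is kept.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_restarts: int = 100,
        n_virtual_samples: int = 100,
        virtual_length: int = 3,
        rep_states: int | None = None,  # default: median rule
        max_iter: int = 20,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.n_virtual_samples = n_virtual_samples
        self.virtual_length = virtual_length
        self.rep_states = rep_states
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, hmms) -> "HMMClusterer":
        n = len(hmms)
        if n < self.n_clusters:
            raise ValueError("need at least n_clusters HMMs")
        params = [hmm_params(h) for h in hmms]
        hashes = [_content_hash(p) for p in params]
        order = np.argsort(hashes, kind="stable")  # canonical, order-independent
        seed = 0 if self.random_state is None else int(self.random_state)
        ks = [np.asarray(p["prior"]).shape[0] for p in params]
        K_rep = self.rep_states or int(np.ceil(np.median(ks)))
        virtual = []
        for i in order:
            rng = np.random.default_rng(np.random.SeedSequence([seed, hashes[i]]))
            virtual.append(sample_hmm_sequences(params[i], self.n_virtual_samples, self.virtual_length, rng))
        best = None
        for r in range(self.n_restarts):
            labels = np.array(
                [
                    np.random.default_rng(np.random.SeedSequence([seed, r, hashes[i]])).integers(self.n_clusters)
                    for i in order
                ]
            )
            labels, reps, ll, obj = self._hard_em(virtual, labels, K_rep, seed, r)
            if best is None or obj > best[3]:
                best = (labels, reps, ll, obj)
        labels_sorted, reps, ll_sorted, obj = best
        if len(np.unique(labels_sorted)) < self.n_clusters:
            warnings.warn("clustering degenerated to fewer non-empty clusters than requested")
        # undo the canonical ordering
        labels = np.empty(n, dtype=int)
        logliks = np.empty((n, self.n_clusters))
        for pos, i in enumerate(order):
            labels[i] = labels_sorted[pos]
            logliks[i] = ll_sorted[pos]
        self.labels_ = labels
        self.representatives_ = reps
        self.logliks_ = logliks
        self.objective_ = obj
        self.rep_states_ = K_rep
        return self

    def _fit_rep(self, member_seqs: list, K: int, seed: int, r: int, c: int):
        X = np.concatenate(member_seqs, axis=0)
        model = VariationalGaussianHMM(
            n_states=K,
            n_restarts=2,
            random_state=int(np.random.SeedSequence([seed, 1000 + r, c]).generate_state(1)[0] % (2**31)),
        )
        model.fit(list(X))
        return hmm_params(model)

    def _hard_em(self, virtual: list, labels: np.ndarray, K_rep: int, seed: int, r: int):
        n = len(virtual)
        reps = [None] * self.n_clusters
        ll = np.full((n, self.n_clusters), -np.inf)
        obj = -np.inf
        for _ in range(self.max_iter):
            for c in range(self.n_clusters):
                members = [virtual[i] for i in range(n) if labels[i] == c]
                if not members:  # re-seed an empty cluster with the worst-fitting HMM
                    worst = int(np.argmin([ll[i, labels[i]] for i in range(n)]))
                    labels[worst] = c
                    members = [virtual[worst]]
                reps[c] = self._fit_rep(members, K_rep, seed, r, c)
            for i in range(n):
                for c in range(self.n_clusters):
                    ll[i, c] = np.mean([forward_loglik(reps[c], s) for s in virtual[i]])
            new_labels = ll.argmax(axis=1)
            obj = float(ll[np.arange(n), new_labels].sum())
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        return labels, reps, ll, obj


def vhem_cluster(
    hmms,
    n_clusters: int = 2,
    restarts: int = 100,
    n_virtual_samples: int = 100,
    rng_seed: int | None = None,
    data_sequences=None,
    **kwargs,
) -> ClusterResult:
    """Cluster individual HMMs into representative patterns.

    If ``data_sequences`` (per individual, a list/array of sequences)
    is given, the reported per-individual log-likelihoods and AB scale
    use those observed sequences; otherwise the virtual samples stand
    in for them.
    """
    clusterer = HMMClusterer(
        n_clusters=n_clusters,
        n_restarts=restarts,
        n_virtual_samples=n_virtual_samples,
        random_state=rng_seed,
        **kwargs,
    ).fit(hmms)
    logliks = clusterer.logliks_
    if data_sequences is not None:
        logliks = np.array(
            [
                [mean_sequence_loglik(rep, seqs) for rep in clusterer.representatives_]
                for seqs in data_sequences
            ]
        )
    scale = np.array([ab_scale(a, b) for a, b in logliks[:, :2]]) if n_clusters >= 2 else np.zeros(len(hmms))
    return ClusterResult(
        representatives=clusterer.representatives_,
        assignment=clusterer.labels_,
        logliks=logliks,
        ab_scale=scale,
        objective=clusterer.objective_,
    )


def ab_scale(loglik_a: float, loglik_b: float) -> float:
    """Pattern-contrast scale (A - B) / (|A| + |B|), in [-1, 1].

    Positive values mean the individual's data are more A-like.  For
    eyes- vs nose-focused face-viewing patterns this is the EN scale.
    """
    denom = abs(loglik_a) + abs(loglik_b)
    if denom == 0:
        raise ValueError("AB scale undefined: both log-likelihoods are zero")
    return float((loglik_a - loglik_b) / denom)


# ---------------------------------------------------------------------------
# overall entropy
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EntropyReport:
    total: float  # nats
    discrete_component: float  # prior + transition terms, >= 0
    differential_component: float  # Gaussian emission terms
    T: int
    normalized: float  # total / T

    def __float__(self):
        return self.total


def _discrete_entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def overall_entropy(model, T: int = 3, include_scale: bool = True) -> EntropyReport:
    """Joint entropy of a T-fixation sequence under an HMM, in nats.

    total = H(Z_1) + sum_{t=2..T} E[H(Z_t | Z_{t-1})]
          + sum_{t=1..T} sum_z P(Z_t = z) * h(N_z),

    where h is the Gaussian differential entropy 0.5*ln((2*pi*e)^d |S|)
    and the marginal state occupancies come from powers of the
    transition matrix applied to the prior.  Lower values mean a more
    consistent (more predictable) strategy.
    """
    params = hmm_params(model, include_scale=include_scale)
    pi = np.asarray(params["prior"], dtype=float)
    A = np.asarray(params["transition"], dtype=float)
    covs = np.asarray(params["covariances"], dtype=float)
    d = covs.shape[-1]
    h_emit = np.empty(covs.shape[0])
    for k, c in enumerate(covs):
        sign, logdet = np.linalg.slogdet(c)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular emission covariance")
        h_emit[k] = 0.5 * (d * (1.0 + _LOG2PI) + logdet)
    marginals = [pi]
    for _ in range(T - 1):
        marginals.append(marginals[-1] @ A)
    discrete = _discrete_entropy(pi)
    for t in range(1, T):
        discrete += float(sum(marginals[t - 1][j] * _discrete_entropy(A[j]) for j in range(len(pi))))
    differential = float(sum(m @ h_emit for m in marginals))
    total = discrete + differential
    return EntropyReport(
        total=total,
        discrete_component=discrete,
        differential_component=differential,
        T=T,
        normalized=total / T,
    )
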