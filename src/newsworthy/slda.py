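"""Supervised latent Dirichlet allocation (sLDA) with a softmax response.

Generative story for an article with N words and a binary label:

  1. draw topic proportions  theta ~ Dirichlet(alpha),
  2. for each word position n: draw a topic  z_n ~ Multinomial(theta)
     and a word  w_n ~ Multinomial(beta_{z_n}),
  3. draw the class label  c ~ softmax(eta_c' zbar)  where
     zbar_k = (1/N) sum_n 1[z_n = k]  are the empirical topic frequencies.

The label depends on the topics actually used in the document, so fitting
pulls the topics toward axes that separate the classes — here, articles
that did vs. did not receive a press release or news coverage.

Fitting is by variational EM.  The per-document E-step runs coordinate
ascent on a fully factorized posterior q(theta) q(z) = Dirichlet(gamma)
prod_n Multinomial(phi_n).  The intractable softmax normalizer
E_q[log sum_c exp(eta_c' zbar)] is handled with the standard two-stage
bound: Jensen's inequality moves the expectation inside the log
(the product over positions then factorizes over phi_n), and a first-order
log bound (log x <= x/zeta + log zeta - 1, tight at zeta = current value)
makes the per-position update closed-form.  Both are minorize-maximize
steps, so the reported evidence lower bound is non-decreasing across EM
iterations.  With the binary reference-class convention eta_neg = 0, the
label term of the bound per document is

    y * eta' phibar  -  log(1 + prod_n phi_n' exp(eta / N)).

The M-step updates beta in closed form from expected topic-word counts and
eta by L-BFGS on the (concave) response term of the bound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.special import softmax

logger = logging.getLogger("newsworthy")


# ------------------------------------------------------------------ model

@dataclass
class SLDAModel:
    """Topics, response coefficients, and Dirichlet prior of a fitted model.

    ``beta`` is (K, V): each row a distribution over the V vocabulary words.
    ``eta`` is (C, K) with the reference (negative) class row fixed at zero
    for identifiability; ``eta[1]`` drives the positive class.
    """

    K: int
    V: int
    alpha: float
    beta: np.ndarray
    eta: np.ndarray
    C: int = 2
    vocab_words: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.beta.shape != (self.K, self.V):
            raise ValueError(f"beta must be (K={self.K}, V={self.V}); got {self.beta.shape}")
        if self.eta.shape != (self.C, self.K):
            raise ValueError(f"eta must be (C={self.C}, K={self.K}); got {self.eta.shape}")
        if np.any(self.beta <= 0):
            raise ValueError("beta entries must be strictly positive")
        if not np.allclose(self.beta.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("beta rows must sum to 1")
        if np.any(self.eta[0] != 0.0):
            raise ValueError("reference-class eta must be exactly zero")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class DocTopicState:
    """Variational posterior for one document."""

    theta_variational: np.ndarray  # gamma, (K,)
    phi: np.ndarray                # (N, K)
    zbar: np.ndarray               # (K,), mean of phi rows

    def __post_init__(self) -> None:
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("phi rows must sum to 1")


@dataclass
class FitTrace:
    """ELBO trajectory of a variational EM run."""

    elbo: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    seed: int = 0


# --------------------------------------------------------- numba kernels

@njit(cache=False)
def _digamma_nb(x):
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    f = 1.0 / (x * x)
    return (
        r
        + math.log(x)
        - 0.5 / x
        - f * (1.0 / 12.0 - f * (1.0 / 120.0 - f * (1.0 / 252.0 - f * (1.0 / 240.0 - f / 132.0))))
    )


@njit(cache=False)
def _estep_kernel(tokens, doc_ptr, y, log_beta, eta_pos, alpha, phi, gamma,
                  use_label, max_inner, tol):
    """Per-document coordinate ascent on (phi, gamma); updates in place.

    Returns (elbo_total, log_a1) where log_a1[d] = log prod_n phi_n' exp(eta/N)
    is the Jensen factor of the softmax normalizer bound for document d.
    """
    n_docs = doc_ptr.shape[0] - 1
    K = log_beta.shape[0]
    log_a1 = np.zeros(n_docs)
    elbo = 0.0
    for d in range(n_docs):
        s = doc_ptr[d]
        e = doc_ptr[d + 1]
        N = e - s
        invN = 1.0 / N
        e1 = np.empty(K)
        for k in range(K):
            e1[k] = math.exp(eta_pos[k] * invN)
        yd = y[d]
        dig = np.empty(K)
        gsum = 0.0
        for k in range(K):
            gsum += gamma[d, k]
        for k in range(K):
            dig[k] = _digamma_nb(gamma[d, k])
        tmp = np.empty(K)
        la1 = 0.0
        for it in range(max_inner):
            # exact recompute of the Jensen factor each sweep
            la1 = 0.0
            for n in range(s, e):
                u = 0.0
                for k in range(K):
                    u += phi[n, k] * e1[k]
                la1 += math.log(u)
            change = 0.0
            for n in range(s, e):
                w = tokens[n]
                u_old = 0.0
                for k in range(K):
                    u_old += phi[n, k] * e1[k]
                coef = 0.0
                if use_label == 1:
                    # A1/zeta with position n's factor removed
                    a1 = math.exp(la1)
                    coef = (a1 / u_old) / (1.0 + a1)
                mx = -1.0e300
                for k in range(K):
                    v = dig[k] + log_beta[k, w]
                    if use_label == 1:
                        if yd == 1:
                            v += eta_pos[k] * invN
                        v -= coef * e1[k]
                    tmp[k] = v
                    if v > mx:
                        mx = v
                ssum = 0.0
                for k in range(K):
                    tmp[k] = math.exp(tmp[k] - mx)
                    ssum += tmp[k]
                u_new = 0.0
                for k in range(K):
                    nv = tmp[k] / ssum
                    change += abs(nv - phi[n, k])
                    phi[n, k] = nv
                    u_new += nv * e1[k]
                la1 += math.log(u_new) - math.log(u_old)
            # exact coordinate update of gamma
            gsum = 0.0
            for k in range(K):
                g = alpha
                for n in range(s, e):
                    g += phi[n, k]
                gamma[d, k] = g
                gsum += g
            for k in range(K):
                dig[k] = _digamma_nb(gamma[d, k])
            if change * invN < tol:
                break
        log_a1[d] = la1
        # ----- per-document ELBO (with the Jensen softmax bound)
        digsum = _digamma_nb(gsum)
        ld = math.lgamma(K * alpha) - K * math.lgamma(alpha)
        ld -= math.lgamma(gsum)
        for k in range(K):
            elt = dig[k] - digsum
            ld += (alpha - 1.0) * elt
            ld += math.lgamma(gamma[d, k]) - (gamma[d, k] - 1.0) * elt
        for n in range(s, e):
            w = tokens[n]
            for k in range(K):
                p = phi[n, k]
                if p > 1e-300:
                    ld += p * (dig[k] - digsum + log_beta[k, w] - math.log(p))
        if use_label == 1:
            if yd == 1:
                sbar = 0.0
                for k in range(K):
                    pb = 0.0
                    for n in range(s, e):
                        pb += phi[n, k]
                    sbar += eta_pos[k] * pb * invN
                ld += sbar
            # log(1 + a1), stable
            if la1 > 30.0:
                ld -= la1
            else:
                ld -= math.log(1.0 + math.exp(la1))
        elbo += ld
    return elbo, log_a1


@njit(cache=False)
def _topic_word_counts(tokens, phi, V):
    N, K = phi.shape
    C = np.zeros((K, V))
    for n in range(N):
        w = tokens[n]
        for k in range(K):
            C[k, w] += phi[n, k]
    return C


# ----------------------------------------------------------- generation

def sample_corpus(
    model: SLDAModel,
    n_docs: int,
    doc_length,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, list[np.ndarray]]:
    """Sample documents and labels from the generative story.

    ``doc_length`` is an int (all documents equal) or a sequence of per-doc
    word counts.  Returns (documents, labels, theta, z) where documents are
    arrays of token ids and z the true per-position topic assignments.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(doc_length):
        lengths = np.full(n_docs, int(doc_length))
    else:
        lengths = np.asarray(doc_length, dtype=int)
        if lengths.shape[0] != n_docs:
            raise ValueError("doc_length sequence must have n_docs entries")
    if np.any(lengths < 1):
        raise ValueError("document lengths must be >= 1")

    thetas = rng.dirichlet(np.full(model.K, model.alpha), size=n_docs)
    docs: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    labels = np.empty(n_docs, dtype=np.int64)
    for d in range(n_docs):
        N = lengths[d]
        z = rng.choice(model.K, size=N, p=thetas[d])
        w = np.empty(N, dtype=np.int64)
        for k in np.unique(z):
            mask = z == k
            w[mask] = rng.choice(model.V, size=int(mask.sum()), p=model.beta[k])
        zbar = np.bincount(z, minlength=model.K) / N
        probs = softmax(model.eta @ zbar)
        labels[d] = rng.choice(model.C, p=probs)
        docs.append(w)
        zs.append(z)
    return docs, labels, thetas, zs


# -------------------------------------------------------------- fitting

def _pack(documents: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    doc_ptr = np.zeros(len(documents) + 1, dtype=np.int64)
    for d, doc in enumerate(documents):
        if len(doc) == 0:
            raise ValueError(f"document {d} is empty")
        doc_ptr[d + 1] = doc_ptr[d] + len(doc)
    tokens = np.concatenate([np.asarray(d, dtype=np.int64) for d in documents])
    return tokens, doc_ptr


def _eta_objective(eta_pos, phi, tokens_invN, doc_ptr, y, phibar):
    """Negative bound response term and its gradient, vectorized over positions."""
    E = np.exp(np.outer(tokens_invN, eta_pos))      # (total_N, K)
    PU = phi * E
    u = PU.sum(axis=1)                               # (total_N,)
    log_u = np.log(u)
    log_a1 = np.add.reduceat(log_u, doc_ptr[:-1])
    lse = np.logaddexp(0.0, log_a1)                  # log(1 + a1)
    f = float(np.sum(y * (phibar @ eta_pos)) - np.sum(lse))
    sig = np.exp(log_a1 - lse)                       # a1 / (1 + a1), per doc
    w_pos = np.repeat(sig, np.diff(doc_ptr)) * tokens_invN
    grad2 = (PU / u[:, None] * w_pos[:, None]).sum(axis=0)
    grad = (y[:, None] * phibar).sum(axis=0) - grad2
    return -f, -grad


def fit_slda(
    documents: list[np.ndarray],
    labels,
    V: int | None = None,
    K: int = 20,
    alpha: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
    inner_max_iter: int = 100,
    inner_tol: float = 1e-6,
    supervised: bool = True,
    beta_smoothing: float = 1e-8,
    vocab_words: list[str] | None = None,
) -> tuple[SLDAModel, list[DocTopicState], FitTrace]:
    """Fit sLDA by variational EM.

    With ``supervised=False`` the label term is dropped and the procedure is
    plain variational LDA.  All randomness (topic initialization) derives
    from ``seed``; identical inputs and seed give identical traces.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    if len(documents) != labels.shape[0]:
        raise ValueError("documents and labels must have equal length")
    if supervised and np.unique(labels).size < 2:
        raise ValueError("labels must cover at least 2 classes")
    tokens, doc_ptr = _pack(documents)
    if V is None:
        V = int(tokens.max()) + 1
    if tokens.max() >= V or tokens.min() < 0:
        raise ValueError("token ids must lie in [0, V)")

    rng = np.random.default_rng(seed)
    n_docs = len(documents)
    total_N = tokens.shape[0]

    # beta init: word counts of randomly selected documents, smoothed
    beta = np.empty((K, V))
    pick = rng.choice(n_docs, size=K, replace=n_docs < K)
    for k in range(K):
        counts = np.bincount(tokens[doc_ptr[pick[k]]:doc_ptr[pick[k] + 1]], minlength=V).astype(float)
        counts += 0.5 + 0.5 * rng.random(V)  # seeded perturbation breaks symmetry
        beta[k] = counts / counts.sum()

    # phi init: randomly perturbed uniform (then warm-started across iterations)
    phi = np.full((total_N, K), 1.0 / K) * (1.0 + 0.01 * rng.random((total_N, K)))
    phi /= phi.sum(axis=1, keepdims=True)
    gamma = np.full((n_docs, K), alpha) + np.diff(doc_ptr)[:, None] / K

    eta_pos = np.zeros(K)
    tokens_invN = np.repeat(1.0 / np.diff(doc_ptr), np.diff(doc_ptr))
    y = labels.astype(np.int64)
    use_label = 1 if supervised else 0

    trace = FitTrace(seed=seed)
    prev = -np.inf
    for it in range(max_iter):
        elbo, _ = _estep_kernel(
            tokens, doc_ptr, y, np.log(beta), eta_pos, alpha, phi, gamma,
            use_label, inner_max_iter, inner_tol,
        )
        if not np.isfinite(elbo):
            raise RuntimeError(f"non-finite ELBO at EM iteration {it}: {elbo}")
        trace.elbo.append(float(elbo))
        trace.n_iter = it + 1
        if prev > -np.inf and abs(elbo - prev) < tol * abs(prev):
            trace.converged = True
            break
        prev = elbo

        # M-step: beta from expected topic-word counts
        Ckv = _topic_word_counts(tokens, phi, V)
        beta = Ckv + beta_smoothing
        beta /= beta.sum(axis=1, keepdims=True)

        # M-step: eta by L-BFGS on the concave response bound
        if supervised:
            phibar = np.add.reduceat(phi, doc_ptr[:-1], axis=0) / np.diff(doc_ptr)[:, None]
            res = minimize(
                _eta_objective, eta_pos, method="L-BFGS-B", jac=True,
                args=(phi, tokens_invN, doc_ptr, y, phibar),
                options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-8},
            )
            eta_pos = res.x

    eta = np.vstack([np.zeros(K), eta_pos])
    model = SLDAModel(K=K, V=V, alpha=alpha, beta=beta, eta=eta, vocab_words=vocab_words)
    states = []
    for d in range(n_docs):
        ph = phi[doc_ptr[d]:doc_ptr[d + 1]]
        states.append(DocTopicState(theta_variational=gamma[d].copy(), phi=ph.copy(),
                                    zbar=ph.mean(axis=0)))
    logger.info("sLDA fit: %d EM iterations, ELBO %.2f, converged=%s",
                trace.n_iter, trace.elbo[-1], trace.converged)
    return model, states, trace


def infer_document(model: SLDAModel, document, max_iter: int = 100, tol: float = 1e-6) -> DocTopicState:
    """Posterior over theta and z for one document, ignoring the label term."""
    doc = np.asarray(document, dtype=np.int64)
    if doc.size == 0:
        raise ValueError("document is empty")
    if doc.max() >= model.V or doc.min() < 0:
        raise ValueError("unknown token id in document")
    tokens, doc_ptr = _pack([doc])
    phi = np.full((doc.size, model.K), 1.0 / model.K)
    gamma = np.full((1, model.K), model.alpha + doc.size / model.K)
    _estep_kernel(
        tokens, doc_ptr, np.zeros(1, dtype=np.int64), np.log(model.beta),
        model.eta[1].astype(float), model.alpha, phi, gamma, 0, max_iter, tol,
    )
    return DocTopicState(theta_variational=gamma[0], phi=phi, zbar=phi.mean(axis=0))


def predict_label(model: SLDAModel, document) -> np.ndarray:
    """Per-class probabilities softmax_c(eta_c' zbar) for an unlabeled document."""
    state = infer_document(model, document)
    return softmax(model.eta @ state.zbar)


def topic_report(model: SLDAModel, doc_states: list[DocTopicState], top_m: int = 10) -> list[dict]:
    """Per-topic coefficient, top words, and corpus prevalence.

    Topics are sorted by their positive-class coefficient, descending (the
    reference class is pinned at zero); with all-zero coefficients the
    order falls back to topic index.  Top words sort by probability, ties
    lexicographically by word string (or by token id without a vocabulary).
    """
    prevalence = np.mean([s.zbar for s in doc_states], axis=0) if doc_states else np.zeros(model.K)
    words = model.vocab_words
    report = []
    for k in range(model.K):
        row = model.beta[k]
        if words is not None:
            order = sorted(range(model.V), key=lambda v: (-row[v], words[v]))
            top = [words[v] for v in order[:top_m]]
        else:
            order = sorted(range(model.V), key=lambda v: (-row[v], v))
            top = [str(v) for v in order[:top_m]]
        report.append({
            "topic": k,
            "coefficient": float(model.eta[1, k]),
            "prevalence": float(prevalence[k]),
            "top_words": top,
        })
    report.sort(key=lambda r: (-r["coefficient"], r["topic"]))
    return report
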