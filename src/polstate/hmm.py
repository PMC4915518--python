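"""K-state multivariate Gaussian-emission HMM over binned enrichment matrices.

The model follows the statsmodels convention: :class:`PhosphoHMM` is built
from the data (an :class:`~polstate.tracks.EnrichmentMatrix` or raw
sequences), ``fit`` runs Baum-Welch expectation maximization and returns a
:class:`PhosphoHMMResults` carrying the parameter estimates, the
log-likelihood trace, Viterbi decoding, the mean-squared-error diagnostic and
a ``summary()`` table.  ``select_n_states`` sweeps K and picks the elbow of
the MSE-versus-K curve.

Each (chromosome, strand) sequence is modeled as an independent Markov chain
sharing one parameter set; ``concatenate=True`` instead joins all sequences
into one literal chain.  Observations x_n are the 5-mark log-enrichment
vectors per 20-nt bin; emissions are N(mu_i, Sigma_i) with full symmetric
covariance, regularized by +1e-4*I at every M-step.

The mean squared error reported for a decoded path z is

    MSE = (1 / (5 * n_bins)) * sum_n || x_n - mu_{z_n} ||^2,

i.e. the per-scalar-dimension squared residual; for a genome with two
equal-length strands of N bins each this equals (1/10N) * sum over both
strands of the squared residual norms.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from . import _hmm_kernels
from .tracks import MARKS, EnrichmentMatrix, StatePath

DEFAULT_N_STATES = 8
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 300
COV_REG = 1e-4


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    """Initial distribution, transition matrix and per-state Gaussians."""

    startprob: np.ndarray     # (K,)
    transmat: np.ndarray      # (K, K)
    means: np.ndarray         # (K, D)
    covariances: np.ndarray   # (K, D, D)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        K = self.n_states
        if self.startprob.shape != (K,) or not np.isclose(self.startprob.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must be a length-K probability vector")
        if self.transmat.shape != (K, K):
            raise ValueError("transition matrix must be K x K")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.transmat < 0) or np.any(self.startprob < 0):
            raise ValueError("negative probabilities")
        for i, c in enumerate(self.covariances):
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValueError(f"covariance {i} not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(f"covariance {i} not positive-definite")

    def to_dict(self) -> dict:
        return {"startprob": self.startprob.tolist(),
                "transmat": self.transmat.tolist(),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(startprob=np.asarray(d["startprob"]),
                   transmat=np.asarray(d["transmat"]),
                   means=np.asarray(d["means"]),
                   covariances=np.asarray(d["covariances"]))


def _log_gaussian(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(N, K) log N(x_n | mu_k, Sigma_k) via per-state Cholesky factors."""
    N, D = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    const = D * np.log(2 * np.pi)
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        dev = (X - means[k]).T
        y = solve_triangular(L, dev, lower=True, check_finite=False)
        quad = np.einsum("dn,dn->n", y, y)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (quad + logdet + const)
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _as_sequences(X) -> tuple[list[np.ndarray], list]:
    if isinstance(X, EnrichmentMatrix):
        return X.sequences(), X.keys()
    if isinstance(X, np.ndarray):
        return [np.asarray(X, dtype=float)], [("seq", "+")]
    seqs = [np.asarray(s, dtype=float) for s in X]
    return seqs, [(f"seq{i}", "+") for i in range(len(seqs))]


class PhosphoHMM:
    """HMM over per-bin 5-mark enrichment observations.

    Parameters
    ----------
    X : EnrichmentMatrix, ndarray or list of ndarrays
        Observation sequences; each row is one 20-nt bin.
    n_states : int
        Number of hidden phosphorylation states K.
    covariance_reg : float
        Ridge added to every M-step covariance (guards degenerate clusters).
    concatenate : bool
        Join all (chromosome, strand) sequences into one literal chain
        instead of modeling them as independent chains sharing parameters.
    """

    def __init__(self, X, n_states: int = DEFAULT_N_STATES,
                 covariance_reg: float = COV_REG, concatenate: bool = False):
        seqs, keys = _as_sequences(X)
        seqs = [s for s in seqs if s.shape[0] > 0]
        if not seqs:
            raise ValueError("no observations")
        if concatenate:
            seqs = [np.concatenate(seqs, axis=0)]
            keys = [("concatenated", "+")]
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        self.X = X
        self.sequences = seqs
        self.keys = keys
        self.n_states = n_states
        self.covariance_reg = covariance_reg
        self.concatenate = concatenate
        self.n_obs = int(sum(s.shape[0] for s in seqs))
        self.n_features = seqs[0].shape[1]

    # -- initialization ----------------------------------------------------

    def init_params(self, seed: int = 0,
                    self_transition: float = 0.9) -> HMMParams:
        """Persistence-biased random transitions; means from K-means on the
        pooled bins; covariances from the K-means clusters (+reg); uniform
        initial distribution.

        The random off-diagonal transition mass is drawn uniform and scaled
        to 1 - ``self_transition``.  Chromatin/phosphorylation states persist
        over many consecutive bins, and seeding that persistence lets the
        dynamic likelihood discriminate parameter basins from the first EM
        iterations (a flat random transition matrix makes early EM behave
        like a static mixture, which systematically merges rare states under
        the dominant untranscribed cluster).  ``self_transition=0`` recovers
        the plain uniform-random initialization.
        """
        K = self.n_states
        if self.n_obs < K:
            raise ValueError("fewer bins than states")
        rng = np.random.default_rng(seed)
        trans = rng.uniform(size=(K, K))
        np.fill_diagonal(trans, 0.0)
        if K > 1:
            trans = trans / trans.sum(axis=1, keepdims=True) * (1.0 - self_transition)
            np.fill_diagonal(trans, self_transition)
        else:
            trans = np.ones((1, 1))
        pooled = np.concatenate(self.sequences, axis=0)
        km = KMeans(n_clusters=K, n_init=1, random_state=int(seed) % (2**31),
                    init="k-means++").fit(pooled)
        means = km.cluster_centers_.copy()
        labels = km.labels_.copy()
        # deterministic re-seed rule for an empty cluster: move in the point
        # farthest from its assigned centroid
        for k in range(K):
            if not np.any(labels == k):
                d = np.linalg.norm(pooled - means[labels], axis=1)
                far = int(np.argmax(d))
                means[k] = pooled[far]
                labels[far] = k
        covs = np.empty((K, self.n_features, self.n_features))
        for k in range(K):
            pts = pooled[labels == k]
            if pts.shape[0] >= 2:
                covs[k] = np.cov(pts, rowvar=False)
            else:
                covs[k] = np.cov(pooled, rowvar=False)
            covs[k] += self.covariance_reg * np.eye(self.n_features)
        params = HMMParams(startprob=np.full(K, 1.0 / K), transmat=trans,
                           means=means, covariances=covs)
        params.validate()
        return params

    # -- EM ----------------------------------------------------------------

    def _e_step(self, params: HMMParams, iteration: int):
        K, D = params.n_states, params.n_features
        total_ll = 0.0
        start = np.zeros(K)
        g_sum = np.zeros(K)
        g_x = np.zeros((K, D))
        g_xx = np.zeros((K, D, D))
        xi_sum = np.zeros((K, K))
        for key, Xs in zip(self.keys, self.sequences):
            logB = _log_gaussian(Xs, params.means, params.covariances)
            rowmax = logB.max(axis=1)
            B = np.exp(logB - rowmax[:, None])
            gamma, xi, logc, ok = _hmm_kernels.forward_backward(
                B, params.transmat, params.startprob)
            ll = logc + rowmax.sum()
            if not ok or not np.isfinite(ll):
                raise FitError(f"non-finite likelihood on sequence {key} "
                               f"at EM iteration {iteration}")
            total_ll += ll
            start += gamma[0]
            g_sum += gamma.sum(axis=0)
            g_x += gamma.T @ Xs
            g_xx += np.einsum("nk,ni,nj->kij", gamma, Xs, Xs, optimize=True)
            xi_sum += xi
        return total_ll, start, g_sum, g_x, g_xx, xi_sum

    def fit(self, seed: int = 0, tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAX_ITER,
            params: HMMParams | None = None,
            n_restarts: int = 8, restart_iter: int = 100) -> "PhosphoHMMResults":
        """Baum-Welch EM from a K-means initialization (or given params).

        Unless explicit ``params`` are supplied, EM is restarted
        ``n_restarts`` times from independent K-means initializations (each
        run capped at ``restart_iter`` iterations) and the run with the
        highest HMM log-likelihood is kept and continued to convergence.
        Plain K-means seeds on mass-imbalanced genomes tend to spend several
        states on the dominant untranscribed cluster while merging rare
        states; the dynamic likelihood separates those basins sharply at
        convergence, so restart selection makes the fit reproducible across
        seeds.
        """
        if params is not None or n_restarts <= 1:
            p = params if params is not None else self.init_params(seed)
            trace, p, converged = self._em(p, tol, max_iter)
            return PhosphoHMMResults(model=self, params=p,
                                     loglik_trace=np.array(trace),
                                     converged=converged, seed=seed)
        sub = np.random.default_rng(seed).integers(2**31, size=n_restarts)
        best = None
        for rs in sub:
            p0 = self.init_params(int(rs))
            tr, p1, _ = self._em(p0, tol=tol, max_iter=restart_iter)
            if best is None or tr[-1] > best[0][-1]:
                best = (tr, p1)
        head, p = best
        tail, p, converged = self._em(p, tol, max_iter)
        return PhosphoHMMResults(model=self, params=p,
                                 loglik_trace=np.array(list(head) + list(tail)),
                                 converged=converged, seed=seed)

    def _em(self, p: HMMParams, tol: float, max_iter: int):
        K, D = self.n_states, self.n_features
        trace: list[float] = []
        converged = False
        for it in range(max_iter):
            ll, start, g_sum, g_x, g_xx, xi_sum = self._e_step(p, it)
            trace.append(ll)
            if len(trace) >= 2:
                prev = trace[-2]
                if ll + 1e-6 < prev:
                    warnings.warn(f"log-likelihood decreased at iteration {it}")
                if tol > 0 and abs(ll - prev) < tol * abs(prev):
                    converged = True
                    break
            # M-step
            safe = np.maximum(g_sum, 1e-300)
            means = g_x / safe[:, None]
            covs = g_xx / safe[:, None, None] - np.einsum("ki,kj->kij", means, means)
            covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
            # guard degenerate clusters by flooring eigenvalues at the reg
            # level; healthy covariances pass through exactly, keeping the
            # EM update monotone
            w, V = np.linalg.eigh(covs)
            w = np.maximum(w, self.covariance_reg)
            covs = np.einsum("kij,kj,klj->kil", V, w, V)
            rows = xi_sum.sum(axis=1, keepdims=True)
            trans = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300), 1.0 / K)
            startprob = start / start.sum()
            p = HMMParams(startprob=startprob, transmat=trans, means=means,
                          covariances=covs)
        return trace, p, converged

    def loglikelihood(self, params: HMMParams) -> float:
        """Forward-algorithm log-likelihood of the data under ``params``."""
        return self._e_step(params, 0)[0]

    def select_n_states(self, k_range=range(3, 16), seed: int = 0,
                        tol: float = DEFAULT_TOL,
                        max_iter: int = DEFAULT_MAX_ITER) -> "KSelection":
        """Fit every K in ``k_range`` (fresh initialization seeded seed+K) and
        choose the elbow of the MSE curve (maximum discrete second difference)."""
        ks, mses, results = [], [], {}
        for k in k_range:
            model = PhosphoHMM(self.X, n_states=k,
                               covariance_reg=self.covariance_reg,
                               concatenate=self.concatenate)
            try:
                res = model.fit(seed=seed + k, tol=tol, max_iter=max_iter)
            except Exception as exc:  # noqa: BLE001 - record and skip this K
                warnings.warn(f"fit failed for K={k}: {exc}")
                continue
            ks.append(k)
            mses.append(res.mse)
            results[k] = res
        if not ks:
            raise FitError("every fit in the K sweep failed")
        return KSelection(ks=np.array(ks), mses=np.array(mses), results=results,
                          seed=seed)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class PhosphoHMMResults:
    """Fitted HMM: parameter estimates, EM trace and decoding products."""

    model: PhosphoHMM
    params: HMMParams
    loglik_trace: np.ndarray
    converged: bool
    seed: int
    labels: dict[int, str] | None = None
    _path: StatePath | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.params.n_states

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    def decode(self) -> StatePath:
        """Viterbi state path over the model's own observations (cached)."""
        if self._path is None:
            self._path = viterbi(self.model, self.params)
        return self._path

    @property
    def mse(self) -> float:
        return mse(self.model, self.decode(), self.params)

    def label_states(self, reference) -> dict[int, str]:
        self.labels = label_states(self.params, reference)
        return self.labels

    def summary(self) -> str:
        lines = [
            "Phosphorylation-state HMM results",
            "=" * 64,
            f"states (K):        {self.n_states}",
            f"observations:      {self.model.n_obs} bins x {self.model.n_features} marks",
            f"sequences:         {len(self.model.sequences)}",
            f"log-likelihood:    {self.loglik:.3f}",
            f"EM iterations:     {self.n_iter} ({'converged' if self.converged else 'max_iter reached'})",
            f"MSE (Viterbi):     {self.mse:.4f}",
            f"init seed:         {self.seed}",
            "-" * 64,
            "state  label  occupancy  " + "  ".join(f"{m:>6}" for m in MARKS),
        ]
        freqs = self.decode().state_frequencies()
        for k in range(self.n_states):
            lab = (self.labels or {}).get(k, "-")
            mus = "  ".join(f"{v:6.2f}" for v in self.params.means[k])
            lines.append(f"{k:>5}  {lab:>5}  {freqs[k]:>9.3f}  {mus}")
        return "\n".join(lines)

    def save(self, path) -> None:
        d = {"params": self.params.to_dict(),
             "labels": self.labels,
             "seed": self.seed,
             "converged": self.converged,
             "loglik_trace": np.asarray(self.loglik_trace).tolist(),
             "marks": list(MARKS)}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def load_params(path) -> tuple[HMMParams, dict[int, str] | None]:
        with open(path) as fh:
            d = json.load(fh)
        labels = d.get("labels")
        if labels is not None:
            labels = {int(k): v for k, v in labels.items()}
        return HMMParams.from_dict(d["params"]), labels


@dataclass
class KSelection:
    """MSE-versus-K sweep with the elbow choice."""

    ks: np.ndarray
    mses: np.ndarray
    results: dict
    seed: int

    @property
    def chosen_k(self) -> int:
        """Elbow of the MSE curve: the K with the sharpest proportional
        collapse of marginal improvement.

        Scores each interior K by the second difference of the curve
        normalized by the local improvement scale,
        (d_in - d_out) / (d_in + d_out + eps) with d_in = MSE(K-1) - MSE(K)
        and d_out = MSE(K) - MSE(K+1).  The raw (unnormalized) second
        difference is dominated by the global convexity of any decreasing
        MSE curve and peaks at the smallest K; the normalized form locates
        the level-off point instead.  ``second_differences`` stays available
        for inspection.
        """
        ks, mses = self.ks, self.mses
        if len(ks) == 1:
            return int(ks[0])
        if len(ks) == 2:
            return int(ks[np.argmin(mses)])
        drops = np.maximum(-np.diff(mses), 0.0)
        eps = 1e-2 * max(float(drops.mean()), 1e-12)
        score = (drops[:-1] - drops[1:]) / (drops[:-1] + drops[1:] + eps)
        return int(ks[1:-1][np.argmax(score)])

    def second_differences(self) -> np.ndarray:
        return self.mses[:-2] - 2 * self.mses[1:-1] + self.mses[2:]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"K": self.ks, "mse": self.mses})

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ks, self.mses, "o-")
        ax.axvline(self.chosen_k, ls="--", color="grey")
        ax.set_xlabel("number of states K")
        ax.set_ylabel("MSE")
        return ax


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def init_params(X, K: int, seed: int = 0) -> HMMParams:
    return PhosphoHMM(X, n_states=K).init_params(seed)


def em_fit(X, K: int, seed: int = 0, tol: float = DEFAULT_TOL,
           max_iter: int = DEFAULT_MAX_ITER, concatenate: bool = False,
           **fit_kw) -> PhosphoHMMResults:
    return PhosphoHMM(X, n_states=K, concatenate=concatenate).fit(
        seed=seed, tol=tol, max_iter=max_iter, **fit_kw)


def viterbi(model_or_X, params: HMMParams) -> StatePath:
    """Most probable state sequence per (chromosome, strand) chain."""
    model = (model_or_X if isinstance(model_or_X, PhosphoHMM)
             else PhosphoHMM(model_or_X, n_states=params.n_states))
    logpi = np.log(np.maximum(params.startprob, 1e-300))
    logA = np.log(np.maximum(params.transmat, 1e-300))
    data = {}
    for key, Xs in zip(model.keys, model.sequences):
        logB = _log_gaussian(Xs, params.means, params.covariances)
        data[key] = _hmm_kernels.viterbi(logB, logA, logpi)
    bw = model.X.bin_width if isinstance(model.X, EnrichmentMatrix) else 20
    return StatePath(data=data, n_states=params.n_states, bin_width=bw)


def mse(model_or_X, path: StatePath, params: HMMParams) -> float:
    """Per-scalar-dimension mean squared residual of x_n around mu_{z_n};
    equals the (1/10N) two-strand form when both strands have N bins."""
    model = (model_or_X if isinstance(model_or_X, PhosphoHMM)
             else PhosphoHMM(model_or_X, n_states=params.n_states))
    total = 0.0
    n = 0
    for key, Xs in zip(model.keys, model.sequences):
        z = path.data.get(key)
        if z is None or z.size != Xs.shape[0]:
            raise ValueError(f"path misaligned with observations for {key}")
        dev = Xs - params.means[z]
        total += float(np.einsum("nd,nd->", dev, dev))
        n += Xs.shape[0]
    return total / (model.n_features * n)


def select_k(X, k_range=range(3, 16), seed: int = 0, **kw) -> KSelection:
    return PhosphoHMM(X, n_states=max(k_range)).select_n_states(
        k_range=k_range, seed=seed, **kw)


def match_states(a: HMMParams, b: HMMParams) -> np.ndarray:
    """Optimal assignment of b's states to a's by emission-mean distance.

    Returns ``match`` with ``match[i]`` = index of the b-state paired with
    a-state ``i`` (total Euclidean distance minimized).
    """
    if a.n_states != b.n_states:
        raise ValueError("state counts differ")
    cost = np.linalg.norm(a.means[:, None, :] - b.means[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    match = np.empty(a.n_states, dtype=np.int64)
    match[rows] = cols
    return match


def relabeling_from_match(match: np.ndarray) -> np.ndarray:
    """Permutation that renames b's states into a's frame:
    ``perm[b_state] = a_state``."""
    perm = np.empty_like(match)
    perm[match] = np.arange(match.size)
    return perm


def label_states(params: HMMParams, reference) -> dict[int, str]:
    """Assign biological labels to learned states by optimal matching of
    emission means against a reference signature set (K <= #labels)."""
    ref_means = np.asarray(reference.means, dtype=float)
    labels = list(reference.labels)
    if params.n_states > len(labels):
        raise ValueError("more states than reference labels")
    cost = np.linalg.norm(params.means[:, None, :] - ref_means[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return {int(r): labels[int(c)] for r, c in zip(rows, cols)}
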