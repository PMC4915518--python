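"""Segmentation-agreement statistics.

Per-state Jaccard indices between two segmentations (strands reported
separately), permutation-null P values (add-one estimator over uniform
permutations of one sequence), and multi-initialization agreement of the HMM
against the 1/K random baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import PhosphoHMM, match_states, relabeling_from_match
from .tracks import StatePath


def _check_aligned(a: StatePath, b: StatePath) -> None:
    if set(a.keys()) != set(b.keys()):
        raise ValueError("paths cover different sequences")
    for k in a.keys():
        if a.data[k].size != b.data[k].size:
            raise ValueError(f"paths disagree on length of {k}")
    if a.n_states != b.n_states:
        raise ValueError("paths have different state counts")


def jaccard_per_state(path_a: StatePath, path_b: StatePath,
                      match: np.ndarray | None = None,
                      by_strand: bool = True) -> pd.DataFrame:
    """Per-state Jaccard index J_i = |A_i & B_i| / |A_i | B_i|.

    A_i (B_i) is the set of bins assigned state i by path a (b).  ``match``
    (from :func:`~polstate.hmm.match_states`, a -> b) is applied to b first
    when the two paths come from independent fits.  With ``by_strand`` the
    indices are reported separately for the + and - strands as well as
    combined.
    """
    _check_aligned(path_a, path_b)
    b = path_b if match is None else path_b.relabeled(relabeling_from_match(match))
    K = path_a.n_states
    groups: dict[str, list] = {"all": list(path_a.keys())}
    if by_strand:
        groups["+"] = [k for k in path_a.keys() if k[1] == "+"]
        groups["-"] = [k for k in path_a.keys() if k[1] == "-"]
    rows = []
    for gname, keys in groups.items():
        if not keys:
            continue
        za = np.concatenate([path_a.data[k] for k in keys])
        zb = np.concatenate([b.data[k] for k in keys])
        for i in range(K):
            ai, bi = za == i, zb == i
            union = int(np.sum(ai | bi))
            inter = int(np.sum(ai & bi))
            rows.append({"strand": gname, "state": i,
                         "intersection": inter, "union": union,
                         "jaccard": inter / union if union else np.nan})
    return pd.DataFrame(rows)


def permutation_pvalue(path_a: StatePath, path_b: StatePath,
                       n_perm: int = 1000, seed: int = 0,
                       match: np.ndarray | None = None) -> pd.DataFrame:
    """Permutation P value per state for the observed Jaccard indices.

    The null re-computes each J_i after uniformly permuting path b's bins;
    P_i = (1 + #{null J >= observed J}) / (1 + n_perm), so the smallest
    attainable value is 1/(n_perm+1).  ``at_bound`` marks states where no
    permutation reached the observed index, i.e. P is the attainable bound
    "< 1/(n_perm+1)" rather than an exact tail estimate.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    _check_aligned(path_a, path_b)
    b = path_b if match is None else path_b.relabeled(relabeling_from_match(match))
    za = np.concatenate([path_a.data[k] for k in path_a.keys()])
    zb = np.concatenate([b.data[k] for k in path_a.keys()])
    K = path_a.n_states
    ai = [za == i for i in range(K)]
    obs = np.empty(K)
    for i in range(K):
        bi = zb == i
        union = np.sum(ai[i] | bi)
        obs[i] = (np.sum(ai[i] & bi) / union) if union else np.nan
    rng = np.random.default_rng(seed)
    exceed = np.zeros(K)
    for _ in range(n_perm):
        zp = rng.permutation(zb)
        for i in range(K):
            bi = zp == i
            union = np.sum(ai[i] | bi)
            j = (np.sum(ai[i] & bi) / union) if union else np.nan
            if np.isfinite(obs[i]) and np.isfinite(j) and j >= obs[i]:
                exceed[i] += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"state": np.arange(K), "jaccard": obs, "p_value": p,
                         "at_bound": exceed == 0, "n_perm": n_perm})


@dataclass
class ReproReport:
    """Multi-initialization agreement summary."""

    agreement_matrix: np.ndarray      # (n_runs, n_runs), 1.0 on the diagonal
    mean_agreement: float
    sd_agreement: float
    baseline: float                   # 1/K
    seeds: list[int]
    logliks: list[float]
    failed_seeds: list[int] = field(default_factory=list)
    jaccard: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"mean_agreement": self.mean_agreement,
                "sd_agreement": self.sd_agreement,
                "baseline": self.baseline,
                "n_runs": len(self.seeds),
                "seeds": list(map(int, self.seeds)),
                "logliks": list(map(float, self.logliks)),
                "failed_seeds": list(map(int, self.failed_seeds)),
                "agreement_matrix": self.agreement_matrix.tolist()}


def pairwise_agreement(path_a: StatePath, path_b: StatePath,
                       match: np.ndarray | None = None) -> float:
    """Fraction of bins assigned the same (matched) state by both paths."""
    _check_aligned(path_a, path_b)
    b = path_b if match is None else path_b.relabeled(relabeling_from_match(match))
    za = np.concatenate([path_a.data[k] for k in path_a.keys()])
    zb = np.concatenate([b.data[k] for k in path_a.keys()])
    return float(np.mean(za == zb))


def multi_init_agreement(X, K: int = 8, n_init: int = 10,
                         seeds: list[int] | None = None,
                         first_jaccard: bool = True,
                         **fit_kw) -> ReproReport:
    """Fit the HMM from ``n_init`` different initialization seeds and measure
    cross-run segmentation agreement against the 1/K baseline.

    States are matched between every pair of runs by optimal assignment on
    the emission means before comparing paths.  Failed fits are dropped and
    reported.
    """
    if seeds is None:
        seeds = list(range(1, n_init + 1))
    if len(seeds) < 2:
        raise ValueError("need at least two initializations")
    model = PhosphoHMM(X, n_states=K)
    fits, ok_seeds, failed = [], [], []
    for s in seeds:
        try:
            fits.append(model.fit(seed=int(s), **fit_kw))
            ok_seeds.append(int(s))
        except Exception as exc:  # noqa: BLE001 - report and continue
            warnings.warn(f"fit with seed {s} failed: {exc}")
            failed.append(int(s))
    n = len(fits)
    if n < 2:
        raise RuntimeError("fewer than two successful fits")
    paths = [f.decode() for f in fits]
    agree = np.eye(n)
    pair_vals = []
    for i in range(n):
        for j in range(i + 1, n):
            m = match_states(fits[i].params, fits[j].params)
            a = pairwise_agreement(paths[i], paths[j], match=m)
            agree[i, j] = agree[j, i] = a
            pair_vals.append(a)
    jac = None
    if first_jaccard and n >= 2:
        m = match_states(fits[0].params, fits[1].params)
        jac = jaccard_per_state(paths[0], paths[1], match=m)
    return ReproReport(agreement_matrix=agree,
                       mean_agreement=float(np.mean(pair_vals)),
                       sd_agreement=float(np.std(pair_vals)),
                       baseline=1.0 / K, seeds=ok_seeds,
                       logliks=[f.loglik for f in fits],
                       failed_seeds=failed, jaccard=jac)
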