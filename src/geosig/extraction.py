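"""De novo signature extraction by consensus NMF.

The extraction model mirrors the standard signature-discovery recipe:
each replicate Poisson-resamples the catalogue (after down-weighting
hypermutators), factorizes it with multiplicative-update NMF under the
Kullback-Leibler objective from an NNDSVD-based deterministic
initialization, and replicate solutions are pooled and clustered, one
signature per replicate per cluster, under cosine distance. Per-cluster
silhouette widths give a stability score used to select the number of
signatures: the largest k whose mean stability and per-signature
stabilities clear the configured thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.metrics import silhouette_samples

from .catalogue import CatalogueMatrix
from .decomposition import SignatureMatrix, cosine_similarity

_EPS = np.finfo(float).tiny


def poisson_resample(cat: CatalogueMatrix, seed: int | np.random.Generator) -> CatalogueMatrix:
    """Replace each count by a Poisson draw with mean equal to the count."""
    rng = np.random.default_rng(seed)
    return CatalogueMatrix(cat.schema, cat.sample_ids, rng.poisson(cat.counts))


def renormalize_hypermutators(
    cat: CatalogueMatrix, factor_cap: float = 10.0
) -> tuple[CatalogueMatrix, dict[str, float]]:
    """Rescale hypermutator columns down to ``factor_cap`` x median total.

    Returns the rescaled catalogue and a per-sample scale record mapping
    sample id -> factor by which its column was divided, so attributions
    can be reported back on the original scale.
    """
    if factor_cap <= 1:
        raise ValueError("factor_cap must exceed 1")
    totals = cat.totals()
    if not totals.any():
        raise ValueError("cannot renormalize an all-zero catalogue")
    cap = factor_cap * np.median(totals)
    counts = cat.counts.copy()
    scales: dict[str, float] = {}
    for j, total in enumerate(totals):
        if total > cap:
            factor = total / cap
            counts[:, j] = np.rint(cat.counts[:, j] / factor).astype(np.int64)
            scales[cat.sample_ids[j]] = factor
    return CatalogueMatrix(cat.schema, cat.sample_ids, counts), scales


def nndsvd_min(V: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization, zeros replaced by the
    smallest positive entry of V (deterministic given V)."""
    m, n = V.shape
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        x, y = U[:, j], Vt[j, :]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        xpn, xnn = np.linalg.norm(xp), np.linalg.norm(xn)
        ypn, ynn = np.linalg.norm(yp), np.linalg.norm(yn)
        mp, mn = xpn * ypn, xnn * ynn
        if mp >= mn:
            u = xp / xpn if xpn else xp
            v = yp / ypn if ypn else yp
            sigma = mp
        else:
            u = xn / xnn if xnn else xn
            v = yn / ynn if ynn else yn
            sigma = mn
        W[:, j] = np.sqrt(S[j] * sigma) * u
        H[j, :] = np.sqrt(S[j] * sigma) * v
    positive = V[V > 0]
    floor = positive.min() if positive.size else 1e-6
    W[W <= 0] = floor
    H[H <= 0] = floor
    return W, H


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH)."""
    mask = V > 0
    div = np.sum(WH) - np.sum(V)
    div += np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div)


@dataclass
class NMFSolution:
    """One NMF factorization: column-stochastic W, scaled H, diagnostics."""

    W: np.ndarray
    H: np.ndarray
    objective: float
    iterations: int
    seed: int | None = None
    objective_trace: list[float] = field(default_factory=list, repr=False)


def nmf_kl(
    V: np.ndarray,
    k: int,
    init: str = "nndsvd_min",
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = None,
    check_every: int = 10,
    track_objective: bool = False,
) -> NMFSolution:
    """Multiplicative-update NMF minimizing KL divergence.

    The objective is non-increasing at every update pair; iteration stops
    when its relative decrease over ``check_every`` iterations falls below
    ``tol``. W columns are normalized to sum 1 post-hoc, with the scale
    absorbed into H.
    """
    V = np.asarray(V, dtype=float)
    if np.isnan(V).any():
        raise ValueError("NaN in input matrix")
    if (V < 0).any():
        raise ValueError("input must be nonnegative")
    if not 1 <= k <= min(V.shape):
        raise ValueError(f"k={k} outside [1, {min(V.shape)}]")
    # zero rows make the KL updates degenerate; give them a tiny pseudocount
    V = V.copy()
    zero_rows = ~V.any(axis=1)
    if zero_rows.any():
        V[zero_rows] = 1e-12

    if init == "nndsvd_min":
        W, H = nndsvd_min(V, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(V.mean() / k)
        W = scale * rng.random((V.shape[0], k)) + _EPS
        H = scale * rng.random((k, V.shape[1])) + _EPS
    else:
        raise ValueError(f"unknown init {init!r}")

    obj = kl_divergence(V, W @ H)
    trace = [obj] if track_objective else []
    it = 0
    ones_m = np.ones(V.shape[0])
    ones_n = np.ones(V.shape[1])
    while it < max_iter:
        for _ in range(check_every):
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (V / WH)) / np.maximum(np.outer(W.sum(axis=0), ones_n), _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((V / WH) @ H.T) / np.maximum(np.outer(ones_m, H.sum(axis=1)), _EPS)
            it += 1
            if track_objective:
                trace.append(kl_divergence(V, W @ H))
            if it >= max_iter:
                break
        new_obj = kl_divergence(V, W @ H)
        if obj - new_obj < tol * max(abs(obj), 1.0):
            obj = new_obj
            break
        obj = new_obj

    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return NMFSolution(W=W, H=H, objective=obj, iterations=it, seed=seed,
                       objective_trace=trace)


# ---------------------------------------------------------------------------
# consensus clustering of replicate solutions


def _cluster_replicates(
    solutions: list[np.ndarray],
    k: int,
    rng: np.random.Generator,
    n_restarts: int = 100,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Partition pooled replicate signatures into k clusters, one signature
    per replicate per cluster (exact rectangular assignment per replicate).

    Returns (labels over pooled columns, consensus centroids channels x k,
    total within-cluster cosine distance).
    """
    pooled = np.concatenate(solutions, axis=1)  # channels x (R*k)
    norms = np.linalg.norm(pooled, axis=0)
    unit = pooled / np.maximum(norms, _EPS)
    R = len(solutions)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        pick = rng.choice(pooled.shape[1], size=k, replace=False)
        centroids = unit[:, pick].copy()
        labels = np.empty(pooled.shape[1], dtype=int)
        prev = None
        for _ in range(max_iter):
            cost_total = 0.0
            for r in range(R):
                block = unit[:, r * k : (r + 1) * k]
                cnorm = centroids / np.maximum(
                    np.linalg.norm(centroids, axis=0), _EPS
                )
                cost = 1.0 - block.T @ cnorm  # k x k cosine distance
                rows, cols = linear_sum_assignment(cost)
                labels[r * k + rows] = cols
                cost_total += cost[rows, cols].sum()
            new_centroids = np.zeros_like(centroids)
            for c in range(k):
                members = unit[:, labels == c]
                if members.size:
                    new_centroids[:, c] = members.mean(axis=1)
                else:
                    new_centroids[:, c] = centroids[:, c]
            if prev is not None and np.array_equal(prev, labels):
                centroids = new_centroids
                break
            prev = labels.copy()
            centroids = new_centroids
        if best is None or cost_total < best[0]:
            best = (cost_total, labels.copy(), centroids.copy())
    assert best is not None
    return best[1], best[2], best[0]


@dataclass
class KResult:
    """Consensus solution and diagnostics for one candidate k."""

    k: int
    consensus: np.ndarray  # channels x k, column-stochastic
    stability: np.ndarray  # per-signature mean silhouette
    mean_stability: float
    reconstruction_error: float
    degenerate: bool = False


@dataclass
class ExtractionResults:
    """Results of consensus NMF extraction over a range of k."""

    schema_name: str
    per_k: dict[int, KResult]
    selected_k: int
    n_replicates: int
    config: dict
    sample_ids: list[str]

    @property
    def signatures(self) -> SignatureMatrix:
        """Consensus signatures at the selected k."""
        return self.signatures_at(self.selected_k)

    def signatures_at(self, k: int) -> SignatureMatrix:
        res = self.per_k[k]
        names = [f"{self.schema_name}_{chr(65 + i)}" for i in range(k)]
        from .schemas import get_schema

        return SignatureMatrix(get_schema(self.schema_name), names, res.consensus)

    def plot_stability(self, ax=None):
        """Stability / reconstruction-error profile over the scanned k."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary()
        ax.plot(s["k"], s["mean_stability"], "o-", label="mean stability")
        ax.plot(s["k"], s["reconstruction_error"], "s--",
                label="reconstruction error")
        ax.axvline(self.selected_k, color="grey", lw=1, ls=":")
        ax.set_xlabel("number of signatures k")
        ax.legend()
        return ax

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.per_k):
            r = self.per_k[k]
            rows.append(
                {
                    "k": k,
                    "mean_stability": r.mean_stability,
                    "min_stability": float(r.stability.min()) if r.stability.size else np.nan,
                    "reconstruction_error": r.reconstruction_error,
                    "degenerate": r.degenerate,
                    "selected": k == self.selected_k,
                }
            )
        return pd.DataFrame(rows)


class SignatureExtraction:
    """Consensus-NMF signature extraction model for a catalogue.

    Parameters
    ----------
    catalogue : CatalogueMatrix
        Channels x samples mutation counts.
    k_range : iterable of int
        Candidate numbers of signatures (default 1..20, the conventional
        scan range).
    n_replicates : int
        Poisson-resampled NMF runs per k. 100 by default for desk-scale
        runs; raise to the conventional 500 for production extractions.
    s_min, s_sig : float
        Selection thresholds on mean and per-signature stability.
    factor_cap : float or None
        Hypermutator cap (x median burden); None disables renormalization.
    """

    def __init__(
        self,
        catalogue: CatalogueMatrix,
        k_range=range(1, 21),
        n_replicates: int = 100,
        s_min: float = 0.8,
        s_sig: float = 0.2,
        factor_cap: float | None = 10.0,
        tol: float = 1e-8,
        max_iter: int = 10_000,
        n_restarts: int = 100,
    ) -> None:
        if n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        self.catalogue = catalogue
        self.k_range = [int(k) for k in k_range]
        if any(k < 1 for k in self.k_range):
            raise ValueError("k must be >= 1")
        self.n_replicates = n_replicates
        self.s_min = s_min
        self.s_sig = s_sig
        self.factor_cap = factor_cap
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts

    def fit(self, seed: int = 0) -> ExtractionResults:
        cat = self.catalogue
        V0 = cat.counts.astype(float)
        root = np.random.SeedSequence(seed)
        per_k: dict[int, KResult] = {}
        for k, k_seed in zip(self.k_range, root.spawn(len(self.k_range))):
            rep_seeds = k_seed.spawn(self.n_replicates + 1)
            sols: list[np.ndarray] = []
            for r in range(self.n_replicates):
                rng = np.random.default_rng(rep_seeds[r])
                resampled = poisson_resample(cat, rng)
                if self.factor_cap is not None:
                    resampled, _ = renormalize_hypermutators(
                        resampled, self.factor_cap
                    )
                sol = nmf_kl(
                    resampled.counts,
                    k,
                    tol=self.tol,
                    max_iter=self.max_iter,
                )
                sols.append(sol.W)
            per_k[k] = self._consensus(
                V0, k, sols, np.random.default_rng(rep_seeds[-1])
            )
        selected = self._select(per_k)
        return ExtractionResults(
            schema_name=cat.schema.name,
            per_k=per_k,
            selected_k=selected,
            n_replicates=self.n_replicates,
            config={
                "k_range": self.k_range,
                "s_min": self.s_min,
                "s_sig": self.s_sig,
                "factor_cap": self.factor_cap,
                "tol": self.tol,
                "max_iter": self.max_iter,
                "seed": seed,
            },
            sample_ids=list(cat.sample_ids),
        )

    def _consensus(
        self, V0: np.ndarray, k: int, sols: list[np.ndarray], rng
    ) -> KResult:
        if k == 1:
            pooled = np.concatenate(sols, axis=1)
            centroid = pooled.mean(axis=1)
            consensus = (centroid / centroid.sum())[:, None]
            stab = np.array(
                [np.mean([cosine_similarity(pooled[:, j], centroid)
                          for j in range(pooled.shape[1])])]
            )
            err = _reconstruction_error(V0, consensus)
            return KResult(k, consensus, stab, float(stab.mean()), err)
        labels, centroids, _ = _cluster_replicates(
            sols, k, rng, n_restarts=self.n_restarts
        )
        pooled = np.concatenate(sols, axis=1)
        degenerate = len(np.unique(labels)) < k
        if degenerate:
            stab = np.full(k, -1.0)
            consensus = np.maximum(centroids, 0)
            consensus = consensus / np.maximum(consensus.sum(axis=0), _EPS)
            return KResult(k, consensus, stab, -1.0, np.inf, degenerate=True)
        sil = silhouette_samples(pooled.T, labels, metric="cosine")
        stab = np.array([sil[labels == c].mean() for c in range(k)])
        consensus = np.maximum(centroids, 0)
        consensus = consensus / np.maximum(consensus.sum(axis=0), _EPS)
        err = _reconstruction_error(V0, consensus)
        return KResult(k, consensus, stab, float(stab.mean()), err)

    def _select(self, per_k: dict[int, KResult]) -> int:
        candidates = [
            k
            for k, r in per_k.items()
            if not r.degenerate
            and r.mean_stability >= self.s_min
            and (r.stability >= self.s_sig).all()
        ]
        if candidates:
            return max(candidates)
        # nothing stable enough: fall back to the most stable k
        return max(per_k, key=lambda k: per_k[k].mean_stability)


def _reconstruction_error(V: np.ndarray, W: np.ndarray) -> float:
    """Mean per-sample relative L2 error of the NNLS refit under W."""
    errs = []
    for j in range(V.shape[1]):
        v = V[:, j]
        total = np.linalg.norm(v)
        if total == 0:
            continue
        e, _ = nnls(W, v)
        errs.append(np.linalg.norm(v - W @ e) / total)
    return float(np.mean(errs)) if errs else np.nan


def extract(
    cat: CatalogueMatrix,
    k_range=range(1, 21),
    n_replicates: int = 100,
    seed: int = 0,
    **kwargs,
) -> ExtractionResults:
    """Functional wrapper around :class:`SignatureExtraction`."""
    return SignatureExtraction(
        cat, k_range=k_range, n_replicates=n_replicates, **kwargs
    ).fit(seed=seed)
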