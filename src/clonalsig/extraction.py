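"""De novo signature extraction (NMF) and signature refitting.

A 96 x N matrix of mutation counts (clusters, samples, plus optional
background columns added for statistical power) is factorized as V ~ W H
with W the 96 x k signature matrix and H the k x N exposure matrix, both
nonnegative. The factorization uses multiplicative updates minimizing the
generalized Kullback-Leibler divergence — the natural objective for count
data — with seeded random restarts and a per-iteration monotonicity check.

Per-profile contributions are then obtained by nonnegative least squares
refitting of each observed profile on the extracted signatures, and the
quality of the reconstruction is summarized as the cosine similarity
between the observed and refit profile (reliability threshold 0.90).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SignatureCatalog
from .profiles import Profile96, cosine_similarity, merged_signature

_EPS = 1e-12


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH), with 0 log 0 := 0."""
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(div)


def _mu_kl_run(
    V: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One multiplicative-update run from a random start.

    Returns (W, H, objective trajectory). The KL objective is asserted
    non-increasing at every iteration (up to floating-point slack) — a
    violated assertion indicates an implementation defect, never data.
    """
    n_channels, n_samples = V.shape
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(_EPS, 1.0, size=(n_channels, rank)) * scale
    H = rng.uniform(_EPS, 1.0, size=(rank, n_samples)) * scale

    trajectory = [_kl_divergence(V, W @ H + _EPS)]
    for _ in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        obj = _kl_divergence(V, W @ H + _EPS)
        prev = trajectory[-1]
        assert obj <= prev + 1e-6 * max(1.0, abs(prev)), (
            f"KL objective increased: {prev} -> {obj}"
        )
        trajectory.append(obj)
        if prev - obj < tol * max(1.0, abs(prev)):
            break
    return W, H, trajectory


def _normalize_wh(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale W columns to sum 1, absorbing the scale into H (WH invariant)."""
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    return W / col, H * col[:, None]


def _letter_names(k: int) -> list[str]:
    """Stable extraction-order names SBSA, SBSB, ..."""
    letters = string.ascii_uppercase
    return [f"SBS{letters[i % 26] * (i // 26 + 1)}" for i in range(k)]


@dataclass
class NMFResult:
    """Outcome of a multi-restart NMF extraction."""

    signatures: np.ndarray  # W, 96 x k, columns sum to 1
    exposures: np.ndarray  # H, k x N
    rank: int
    objectives: list[float]  # final objective per run
    best_run: int
    trajectory: list[float]  # per-iteration objective of the best run
    seed: int
    signature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.signature_names:
            self.signature_names = _letter_names(self.rank)

    def to_catalog(self) -> SignatureCatalog:
        """Extracted signatures as a loadable catalog (COSMIC layout)."""
        return SignatureCatalog(
            signature_names=list(self.signature_names), matrix=self.signatures
        )


def nmf_extract(
    count_matrix: np.ndarray,
    rank: int,
    n_runs: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> NMFResult:
    """De novo NMF extraction with seeded random restarts.

    The best of ``n_runs`` by final KL objective is kept; W is
    column-normalized with the scale absorbed into H.
    """
    V = np.asarray(count_matrix, dtype=float)
    if V.ndim != 2 or V.shape[0] != 96:
        raise ValueError("count matrix must be 96 x N")
    if (V < 0).any():
        raise ValueError("count matrix must be nonnegative")
    if (V.sum(axis=0) == 0).any():
        raise ValueError("count matrix has an all-zero column")
    if not 1 <= rank < min(V.shape):
        raise ValueError(
            f"rank must satisfy 1 <= rank < {min(V.shape)}; for higher ranks add "
            f"more samples (e.g. background count columns)"
        )
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    runs = [
        _mu_kl_run(V, rank, np.random.default_rng(s), max_iter, tol) for s in seeds
    ]
    objectives = [r[2][-1] for r in runs]
    best = int(np.argmin(objectives))
    W, H, trajectory = runs[best]
    W, H = _normalize_wh(W, H)
    return NMFResult(
        signatures=W,
        exposures=H,
        rank=rank,
        objectives=objectives,
        best_run=best,
        trajectory=trajectory,
        seed=seed,
    )


def _match_cosines(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Best-match cosine of each column of A against the columns of B."""
    return np.array(
        [max(cosine_similarity(A[:, i], B[:, j]) for j in range(B.shape[1]))
         for i in range(A.shape[1])]
    )


def select_rank(
    count_matrix: np.ndarray,
    rank_range: range,
    n_runs: int = 5,
    seed: int = 0,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Per-rank diagnostics: reconstruction error and restart reproducibility.

    Reproducibility is the mean best-match cosine between the signatures of
    every pair of restarts — near 1 when the factorization is stable at that
    rank. No rank is chosen automatically; the table is for the user.
    """
    V = np.asarray(count_matrix, dtype=float)
    rows = []
    for rank in rank_range:
        seeds = np.random.SeedSequence(seed).spawn(n_runs)
        runs = [
            _normalize_wh(*r[:2])[0]
            for r in (_mu_kl_run(V, rank, np.random.default_rng(s), max_iter, 1e-8)
                      for s in seeds)
        ]
        result = nmf_extract(V, rank, n_runs=n_runs, seed=seed, max_iter=max_iter)
        pair_cos = [
            _match_cosines(runs[i], runs[j]).mean()
            for i in range(n_runs)
            for j in range(n_runs)
            if i != j
        ]
        rows.append(
            {
                "rank": rank,
                "kl_error": result.trajectory[-1],
                "reproducibility": float(np.mean(pair_cos)) if pair_cos else 1.0,
            }
        )
    return pd.DataFrame(rows)


def match_to_catalog(
    nmf_result: NMFResult,
    catalog: SignatureCatalog,
    merge_groups: dict[str, list[str]] | None = None,
) -> dict[str, tuple[str, float]]:
    """Best catalog match (argmax cosine) for each extracted signature.

    Merged-group columns (equal-weight renormalized means) compete with the
    plain catalog columns.
    """
    columns = {name: catalog.column(name) for name in catalog.signature_names}
    for gname, members in (merge_groups or {}).items():
        columns[gname] = merged_signature(catalog, members)
    matches = {}
    for i, name in enumerate(nmf_result.signature_names):
        w = nmf_result.signatures[:, i]
        best = max(columns, key=lambda c: cosine_similarity(w, columns[c]))
        matches[name] = (best, cosine_similarity(w, columns[best]))
    return matches


@dataclass
class ContributionResult:
    """Per-profile signature contributions from an NNLS refit."""

    signature_names: list[str]
    relative: np.ndarray  # sums to 1
    absolute: np.ndarray  # sums to the profile total
    reconstruction_similarity: float
    reliable: bool
    label: str = ""


def refit_contributions(
    profile: Profile96,
    signatures: np.ndarray,
    signature_names: list[str] | None = None,
    reliability_threshold: float = 0.90,
) -> ContributionResult:
    """Decompose one observed profile on a set of signatures by NNLS.

    ``relative`` are the NNLS coefficients normalized to sum 1; ``absolute``
    is relative times the profile total, so absolute contributions conserve
    the mutation count. ``reconstruction_similarity`` is the cosine between
    the observed profile and its refit; a profile is flagged reliable when
    it reaches the threshold (default 0.90).
    """
    W = np.asarray(signatures, dtype=float)
    if W.shape[0] != 96:
        raise ValueError("signature matrix must be 96 x k")
    names = signature_names or _letter_names(W.shape[1])
    coef, _ = nnls(W, profile.counts.astype(float))
    total = coef.sum()
    if total == 0:
        return ContributionResult(
            signature_names=names,
            relative=np.zeros(W.shape[1]),
            absolute=np.zeros(W.shape[1]),
            reconstruction_similarity=0.0,
            reliable=False,
            label=profile.label,
        )
    relative = coef / total
    recon = W @ coef
    sim = cosine_similarity(profile.counts, recon)
    return ContributionResult(
        signature_names=names,
        relative=relative,
        absolute=relative * profile.total,
        reconstruction_similarity=sim,
        reliable=sim >= reliability_threshold,
        label=profile.label,
    )


def contributions_to_frame(results: list[ContributionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for name, rel, absc in zip(res.signature_names, res.relative, res.absolute):
            rows.append(
                {
                    "cluster": res.label,
                    "signature": name,
                    "relative": rel,
                    "absolute": absc,
                    "reconstruction_similarity": res.reconstruction_similarity,
                    "reliable": res.reliable,
                }
            )
    return pd.DataFrame(rows)


class SignatureNMF(TransformerMixin, BaseEstimator):
    """Sklearn-style front end to the de novo extraction and refit.

    Follows the sklearn sample orientation: ``X`` is N x 96 (samples as
    rows), internally transposed to the 96 x N count matrix. ``fit``
    extracts ``n_components`` signatures; ``transform`` returns the N x k
    relative contributions of each row profile by NNLS refit.

    Fitted attributes: ``components_`` (k x 96 signatures, rows sum to 1),
    ``signature_names_``, ``result_`` (the full :class:`NMFResult`).
    """

    def __init__(
        self,
        n_components: int = 2,
        n_runs: int = 10,
        max_iter: int = 2000,
        tol: float = 1e-9,
        random_state: int = 0,
        reliability_threshold: float = 0.90,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.reliability_threshold = reliability_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.result_ = nmf_extract(
            X.T,
            rank=self.n_components,
            n_runs=self.n_runs,
            seed=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.components_ = self.result_.signatures.T
        self.signature_names_ = self.result_.signature_names
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], self.n_components))
        for i, row in enumerate(X):
            res = refit_contributions(
                Profile96(counts=row, label=str(i)),
                self.result_.signatures,
                self.signature_names_,
                self.reliability_threshold,
            )
            out[i] = res.relative
        return out

    def reconstruction_similarities(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array(
            [
                refit_contributions(
                    Profile96(counts=row, label=str(i)),
                    self.result_.signatures,
                    self.signature_names_,
                    self.reliability_threshold,
                ).reconstruction_similarity
                for i, row in enumerate(X)
            ]
        )
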