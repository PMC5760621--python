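"""Joint learning (JL) of per-protein target-prediction models.

One linear scoring model per target protein, f_m(x) = w_m' x, on
chemical-treatment features, with all M models fitted simultaneously under a
protein-similarity coupling derived from genetic-perturbation signatures
(knock-down profiles for inhibition models, over-expression profiles for
activation models). The coupling lets proteins with few known ligands borrow
strength from transcriptionally similar, well-annotated proteins.

The objective is squared loss on +/-1 labels with a ridge penalty and a
similarity-weighted fusion penalty:

    min_W  sum_m ||y_m - X w_m||^2 + lam1 sum_m ||w_m||^2
           + lam2 sum_{m<m'} S_mm' ||w_m - w_m'||^2

whose stationarity condition is the Sylvester-type linear system

    (X'X + lam1 I) W + lam2 W L = X'Y,      L = diag(S 1) - S.

With every compound labelled for every protein the system is solved exactly
by eigendecomposition of L (one ridge solve per eigencomponent, shared
eigenbasis of X'X). With a pair mask (e.g. balanced negative subsampling)
the per-protein designs differ and the coupled block system is solved by
conjugate gradients instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.linalg import LinearOperator, cg

from .errors import ConfigurationError, SigtargetError
from .gold_standard import LabelMatrix
from .signatures import AggregatedProfile

logger = logging.getLogger(__name__)

#: relative stationarity-residual bound for the exact solver
RESIDUAL_TOL = 1e-6


@dataclass
class FeatureMatrix:
    """Entities x features, rows being aggregated profiles phi(X_i)."""

    ids: tuple[str, ...]
    X: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ConfigurationError("feature matrix shape does not match ids")
        if not np.all(np.isfinite(self.X)):
            raise ConfigurationError("non-finite feature values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_profiles(
        cls,
        profiles: Mapping[str, AggregatedProfile],
        order: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        ids = tuple(order) if order is not None else tuple(profiles)
        return cls(ids, np.vstack([profiles[i].values for i in ids]))

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        index = {e: i for i, e in enumerate(self.ids)}
        rows = [index[e] for e in ids]
        return FeatureMatrix(tuple(ids), self.X[rows], self.feature_names)


@dataclass
class ProteinSimilarity:
    """Symmetric protein-protein similarity in [0, 1], unit diagonal."""

    proteins: tuple[str, ...]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        M = len(self.proteins)
        if self.S.shape != (M, M):
            raise ConfigurationError("similarity matrix shape mismatch")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ConfigurationError("similarity matrix must be symmetric")
        if (self.S < -1e-12).any() or (self.S > 1 + 1e-12).any():
            raise ConfigurationError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ConfigurationError("similarity diagonal must be 1")

    def reorder(self, proteins: Sequence[str]) -> "ProteinSimilarity":
        index = {p: i for i, p in enumerate(self.proteins)}
        idx = [index[p] for p in proteins]
        return ProteinSimilarity(tuple(proteins), self.S[np.ix_(idx, idx)])

    def laplacian(self) -> np.ndarray:
        return np.diag(self.S.sum(axis=1)) - self.S


def build_protein_similarity(
    profiles: Mapping[str, AggregatedProfile] | FeatureMatrix,
) -> ProteinSimilarity:
    """Clipped-correlation similarity of genetic-perturbation profiles.

    S_mm' = max(0, corr(psi_m, psi_m')) with the diagonal forced to 1.
    Proteins with a constant profile get an identity row (no coupling),
    logged.
    """
    if isinstance(profiles, FeatureMatrix):
        ids, P = list(profiles.ids), profiles.X
    else:
        ids = list(profiles)
        P = np.vstack([profiles[p].values for p in ids])
    sd = P.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning(
            "%d protein profile(s) constant; similarity row set to identity",
            int(const.sum()),
        )
    safe = P.copy()
    safe[const] = np.arange(P.shape[1], dtype=float)  # placeholder; rows zeroed below
    S = np.clip(np.corrcoef(safe), 0.0, 1.0)
    S[const, :] = 0.0
    S[:, const] = 0.0
    np.fill_diagonal(S, 1.0)
    return ProteinSimilarity(tuple(ids), S)


@dataclass
class JLModel:
    mode: str | None
    proteins: tuple[str, ...]
    W: np.ndarray  # (d, M), column m = w_m
    lam1: float
    lam2: float
    center: np.ndarray | None = None  # training feature mean (length d)
    n_features: int = field(init=False)
    feature_hash: str | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape[1] != len(self.proteins):
            raise ConfigurationError("weight columns must match proteins")
        if not np.all(np.isfinite(self.W)):
            raise SigtargetError("non-finite weights")
        self.n_features = self.W.shape[0]
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)
            if self.center.shape != (self.n_features,):
                raise ConfigurationError("center length must match features")

    # -- persistence --------------------------------------------------------

    def save(self, weights_path: str | Path, meta_path: str | Path) -> None:
        pd.DataFrame(self.W, columns=list(self.proteins)).to_csv(
            weights_path, sep="\t", index=False
        )
        meta = {
            "mode": self.mode,
            "lam1": self.lam1,
            "lam2": self.lam2,
            "n_features": self.n_features,
            "feature_hash": self.feature_hash,
            "proteins": list(self.proteins),
            "center": None if self.center is None else self.center.tolist(),
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, weights_path: str | Path, meta_path: str | Path) -> "JLModel":
        meta = json.loads(Path(meta_path).read_text())
        W = pd.read_csv(weights_path, sep="\t").to_numpy(dtype=float)
        center = meta.get("center")
        model = cls(
            meta["mode"], tuple(meta["proteins"]), W, meta["lam1"], meta["lam2"],
            center=None if center is None else np.asarray(center, dtype=float),
        )
        model.feature_hash = meta.get("feature_hash")
        return model


def feature_hash(names: Sequence[str] | None, n_features: int) -> str:
    payload = "\t".join(names) if names else f"d={n_features}"
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def jl_objective(
    W: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    S: np.ndarray,
    lam1: float,
    lam2: float,
    mask: np.ndarray | None = None,
) -> float:
    """Value of the joint objective at W (for diagnostics and tests)."""
    R = Y - X @ W
    if mask is not None:
        R = R * mask
    loss = float((R**2).sum()) + lam1 * float((W**2).sum())
    D = W[:, :, None] - W[:, None, :]  # (d, M, M)
    fusion = 0.5 * float(np.einsum("mk,dmk->", S - np.diag(np.diag(S)), D**2))
    return loss + lam2 * fusion


def fit_joint(
    X: FeatureMatrix,
    Y: LabelMatrix,
    S: ProteinSimilarity,
    lam1: float = 1.0,
    lam2: float = 1.0,
    *,
    standardize: bool = False,
    center: bool = True,
) -> JLModel:
    """Fit all per-protein models jointly; see the module docstring.

    ``Y.mask``, when set (balanced subsampling), restricts the squared loss
    to the masked pairs; the coupled system is then solved iteratively.
    Features are centered on the training mean by default: with +/-1 labels
    an uncentered fit adds the same compound-leverage component
    ``(X'X + lam1 I)^-1 X'1`` to every protein's scores — pure nuisance for
    per-protein ranking and an obstacle to cross-protein sharing. Scores and
    rankings then coincide with a 0/1-coded fit up to scale.
    ``standardize=True`` additionally scales each feature to unit variance
    (signature inputs are already z-scores, so this is off by default).
    """
    if lam1 <= 0:
        raise ConfigurationError("lam1 must be > 0")
    if lam2 < 0:
        raise ConfigurationError("lam2 must be >= 0")
    if set(Y.compounds) != set(X.ids):
        raise ConfigurationError("label compounds must match feature ids")
    Xs = X.subset(Y.compounds)
    Sm = S.reorder(Y.proteins)

    A = Xs.X
    if standardize:
        sd = A.std(axis=0)
        A = A / np.where(sd == 0, 1.0, sd)
    mu = A.mean(axis=0) if center else None
    if mu is not None:
        A = A - mu
    Yf = Y.labels.astype(float)
    L = Sm.laplacian()

    if Y.mask is None:
        W = _solve_exact(A, Yf, L, lam1, lam2)
    else:
        W = _solve_masked(A, Yf, Y.mask.astype(float), L, lam1, lam2)

    model = JLModel(Y.mode, Y.proteins, W, lam1, lam2, center=mu)
    model.feature_hash = feature_hash(X.feature_names, X.n_features)
    return model


def _solve_exact(
    A: np.ndarray, Y: np.ndarray, L: np.ndarray, lam1: float, lam2: float
) -> np.ndarray:
    """(A'A + lam1 I) W + lam2 W L = A'Y by eigendecomposition of L."""
    G = A.T @ A
    B = A.T @ Y
    mu, Q = np.linalg.eigh(L)
    mu = np.clip(mu, 0.0, None)  # L is PSD; clip rounding noise
    sig, U = np.linalg.eigh(G)
    sig = np.clip(sig, 0.0, None)
    Bt = U.T @ (B @ Q)  # rotate into both eigenbases
    Wt = Bt / (sig[:, None] + lam1 + lam2 * mu[None, :])
    W = U @ Wt @ Q.T

    resid = G @ W + lam1 * W + lam2 * (W @ L) - B
    rel = np.linalg.norm(resid) / max(np.linalg.norm(B), 1.0)
    if rel > RESIDUAL_TOL:
        raise SigtargetError(f"stationarity residual {rel:.2e} exceeds tolerance")
    return W


def _solve_masked(
    A: np.ndarray,
    Y: np.ndarray,
    mask: np.ndarray,
    L: np.ndarray,
    lam1: float,
    lam2: float,
) -> np.ndarray:
    """Conjugate-gradient solve of the coupled system with per-pair weights."""
    n, d = A.shape
    M = Y.shape[1]

    def matvec(v: np.ndarray) -> np.ndarray:
        W = v.reshape(d, M, order="F")
        out = A.T @ (mask * (A @ W)) + lam1 * W + lam2 * (W @ L)
        return out.ravel(order="F")

    op = LinearOperator((d * M, d * M), matvec=matvec)
    b = (A.T @ (mask * Y)).ravel(order="F")
    v, info = cg(op, b, rtol=1e-10, atol=0.0, maxiter=20_000)
    if info != 0:
        raise SigtargetError(f"conjugate-gradient solver did not converge (info={info})")
    return v.reshape(d, M, order="F")


def predict_scores(model: JLModel, X_new: FeatureMatrix) -> pd.DataFrame:
    """Scores X_new W; higher = stronger predicted interaction of the mode."""
    if X_new.n_features != model.n_features:
        raise ConfigurationError(
            f"feature dimension {X_new.n_features} does not match model "
            f"({model.n_features})"
        )
    X = X_new.X if model.center is None else X_new.X - model.center
    scores = pd.DataFrame(
        X @ model.W, index=list(X_new.ids), columns=list(model.proteins)
    )
    scores.attrs["mode"] = model.mode
    return scores
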