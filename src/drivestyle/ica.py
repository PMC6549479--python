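"""FastICA-type blind source separation for artifact removal.

Symmetric fixed-point iteration with the logcosh contrast and
orthogonal decorrelation; per-component deflation is the fallback when
the symmetric scheme does not converge. Operates on whitened data and
returns mixing/unmixing matrices expressed in sensor space so that
mixing @ unmixing reconstructs the identity on the retained subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ICADecomposition:
    mixing: np.ndarray        # channels x components
    unmixing: np.ndarray      # components x channels
    sources: np.ndarray       # components x samples
    mean: np.ndarray          # per-channel mean removed before unmixing
    converged: bool
    rejected: dict[int, str]  # component index -> reason code


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, 1e-12, None)
    return (u / np.sqrt(s)) @ u.T @ W


def _g_logcosh(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = np.tanh(x)
    return gx, 1.0 - gx ** 2


def _fastica_symmetric(Z: np.ndarray, rng: np.random.Generator,
                       tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    k, n = Z.shape
    W = _sym_decorrelate(rng.standard_normal((k, k)))
    for _ in range(max_iter):
        gx, g_dot = _g_logcosh(W @ Z)
        W1 = _sym_decorrelate(gx @ Z.T / n - g_dot.mean(axis=1)[:, None] * W)
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W1, W)) - 1))
        W = W1
        if delta < tol:
            return W, True
    return W, False


def _fastica_deflation(Z: np.ndarray, rng: np.random.Generator,
                       tol: float, max_iter: int) -> tuple[np.ndarray, int]:
    """Extract components one at a time; returns (W, n_converged)."""
    k, n = Z.shape
    W = np.zeros((k, k))
    n_conv = 0
    for i in range(k):
        w = rng.standard_normal(k)
        w /= np.linalg.norm(w)
        for _ in range(max_iter):
            gx, g_dot = _g_logcosh(w @ Z)
            w1 = Z @ gx / n - g_dot.mean() * w
            w1 -= W[:i].T @ (W[:i] @ w1)  # Gram-Schmidt against found rows
            nrm = np.linalg.norm(w1)
            if nrm < 1e-12:
                break
            w1 /= nrm
            if abs(abs(w1 @ w) - 1) < tol:
                w = w1
                n_conv += 1
                break
            w = w1
        W[i] = w
    return W, n_conv


def fastica(data: np.ndarray, seed: int | None = 0, tol: float = 1e-4,
            max_iter: int = 500) -> ICADecomposition:
    """Decompose channels x samples data into independent components.

    Whitening keeps the full numerical rank. If neither the symmetric
    scheme nor deflation converges the decomposition is returned with
    ``converged=False`` so callers can decline to remove anything.
    """
    X = np.asarray(data, dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    n = Xc.shape[1]
    cov = Xc @ Xc.T / n
    evals, evecs = np.linalg.eigh(cov)
    keep = evals > max(evals[-1], 0) * 1e-10
    evals, evecs = evals[keep], evecs[:, keep]
    whiten = (evecs / np.sqrt(evals)).T        # k x channels
    dewhiten = evecs * np.sqrt(evals)          # channels x k
    Z = whiten @ Xc

    rng = np.random.default_rng(seed)
    W, converged = _fastica_symmetric(Z, rng, tol, max_iter)
    if not converged:
        W, n_conv = _fastica_deflation(Z, rng, tol, max_iter)
        converged = n_conv > 0

    unmixing = W @ whiten
    mixing = dewhiten @ W.T                    # W orthogonal: inverse is W.T
    sources = unmixing @ Xc
    return ICADecomposition(
        mixing=mixing, unmixing=unmixing, sources=sources,
        mean=mean[:, 0], converged=converged, rejected={},
    )
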