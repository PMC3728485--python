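"""Infomax independent component analysis and forward projection.

The decoding method rests on a linear mixing model ``D = M A``: observed data
``D`` (channels x samples for EEG, time points x voxels for spatial fMRI mode)
are an unknown mixture ``M`` of statistically independent activations ``A``.
The unmixing learned on training data is *frozen* and applied to held-out data
by plain matrix multiplication (``A_test = W D_test``) — the train/test
firewall of the whole pipeline.

:class:`InfomaxICA` follows the scikit-learn estimator contract (``fit`` /
``transform`` / ``get_params``) with samples along the first axis, so it
composes with pipelines and model selection.  The algorithm is the classic
natural-gradient logistic Infomax of Bell & Sejnowski (runica-style full-batch
updates with learning-rate annealing), with an optional extended variant that
switches the nonlinearity per component by the sign of its kurtosis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "InfomaxICA",
    "MixingModel",
    "demean",
    "fit_infomax",
    "project_components",
    "amari_index",
]


def demean(data: ArrayLike, axis: int = -1) -> tuple[NDArray, NDArray]:
    """Remove the mean along ``axis`` from each row/slice.

    Returns ``(demeaned, means)`` so the original offsets are recoverable.
    Raises on non-finite input.
    """
    arr = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("data contain non-finite values")
    means = arr.mean(axis=axis, keepdims=True)
    return arr - means, np.squeeze(means, axis=axis)


def amari_index(P: ArrayLike) -> float:
    """Permutation/scale-invariant separation error of a gain matrix.

    ``P = W_recovered @ M_true`` is identity-like (one dominant entry per row
    and column, up to permutation and scale) when separation is perfect; the
    index is 0 then and grows toward 1 as rows/columns lose a dominant entry.
    """
    P = np.abs(np.asarray(P, dtype=float))
    K = P.shape[0]
    if P.shape[1] != K:
        raise ValueError("amari_index requires a square gain matrix")
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * K * (K - 1)))


@dataclass
class MixingModel:
    """Frozen result of an ICA decomposition.

    ``unmixing`` (K x channels) already composes the sphering step, so
    activations on new data are simply ``unmixing @ demeaned_data``.
    ``mixing`` (channels x K) is its pseudoinverse; for a square model
    ``unmixing @ mixing`` is the identity.
    """

    mixing: NDArray
    unmixing: NDArray
    sphering: NDArray
    activations: NDArray | None
    n_iterations: int
    converged: bool
    seed: int | None
    channel_names: list[str] | None = None
    modality: str = "eeg"

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def n_channels(self) -> int:
        return self.unmixing.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to a portable JSON archive (matrices as nested lists)."""
        payload = {
            "mixing": self.mixing.tolist(),
            "unmixing": self.unmixing.tolist(),
            "sphering": self.sphering.tolist(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
            "channel_names": self.channel_names,
            "modality": self.modality,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MixingModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            mixing=np.asarray(payload["mixing"], dtype=float),
            unmixing=np.asarray(payload["unmixing"], dtype=float),
            sphering=np.asarray(payload["sphering"], dtype=float),
            activations=None,
            n_iterations=int(payload["n_iterations"]),
            converged=bool(payload["converged"]),
            seed=payload["seed"],
            channel_names=payload["channel_names"],
            modality=payload.get("modality", "eeg"),
        )


class InfomaxICA(BaseEstimator, TransformerMixin):
    """Natural-gradient logistic Infomax ICA.

    Parameters
    ----------
    n_components : int or None
        Number of components K.  ``None`` keeps K equal to the number of
        channels (square, invertible model).  When K < channels the data are
        first reduced to the top-K principal subspace.
    learning_rate : float
        Initial step size of the natural-gradient ascent (annealed on
        oscillation).
    max_iter : int
        Iteration cap; non-convergence is flagged on the fitted model, never
        raised.
    tol : float
        Convergence tolerance on the Frobenius norm of the weight update.
    extended : bool
        Use the extended nonlinearity with per-component kurtosis-sign
        switching (handles sub-Gaussian sources).  Default is the logistic
        rule.
    anneal : float
        Multiplicative learning-rate decay applied when successive updates
        point in opposing directions (angle > 60 degrees).
    max_samples : int or None
        When set and the data exceed it, the unmixing is estimated on a
        seeded random subset of samples of this size (the final scaling and
        activations still use all samples).  Full-batch estimation on very
        long recordings gains nothing statistically past ~10^4 samples per
        weight.
    random_state : int or None
        Seeds the initial unmixing perturbation (and any subsampling); fits
        are deterministic given data and seed.

    Attributes
    ----------
    unmixing_ : ndarray (K, channels)
        Total unmixing (sphering composed in), scaled so each activation has
        unit variance and positive skewness.
    mixing_ : ndarray (channels, K)
        Pseudoinverse of ``unmixing_``.
    whitening_ : ndarray (K, channels)
        The PCA sphering matrix alone.
    n_iter_ : int, converged_ : bool
    """

    def __init__(
        self,
        n_components: int | None = None,
        learning_rate: float = 0.2,
        max_iter: int = 512,
        tol: float = 1e-7,
        extended: bool = False,
        anneal: float = 0.98,
        max_samples: int | None = None,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol
        self.extended = extended
        self.anneal = anneal
        self.max_samples = max_samples
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: ArrayLike, y=None) -> "InfomaxICA":
        """Learn the unmixing from ``X`` (n_samples, n_channels)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_channels)")
        n_samples, n_chan = X.shape
        K = self.n_components if self.n_components is not None else n_chan
        if K > n_chan:
            raise ValueError(f"n_components={K} exceeds n_channels={n_chan}")
        if n_samples < 2 * n_chan:
            raise ValueError("need substantially more samples than channels")

        D, _ = demean(X.T, axis=-1)  # channels x samples

        # PCA sphering (and reduction when K < channels)
        cov = (D @ D.T) / n_samples
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        rank_tol = n_chan * np.finfo(float).eps * max(evals.max(), 0.0)
        if evals[K - 1] <= max(rank_tol, 0.0) or evals[K - 1] <= 1e-12 * evals[0]:
            raise np.linalg.LinAlgError(
                "data are rank deficient for the requested number of "
                "components; reduce n_components (PCA dimensionality "
                "reduction) before fitting"
            )
        whitening = (evecs[:, :K] / np.sqrt(evals[:K])).T  # K x channels
        Z = whitening @ D  # K x samples, unit covariance

        rng = np.random.default_rng(self.random_state)
        Z_fit = Z
        if self.max_samples is not None and n_samples > self.max_samples:
            Z_fit = Z[:, rng.choice(n_samples, self.max_samples, replace=False)]
        n_fit = Z_fit.shape[1]
        W = np.eye(K) + 1e-3 * rng.standard_normal((K, K))

        lr = float(self.learning_rate)
        prev_delta = None
        signs = np.ones(K)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            U = W @ Z_fit
            if self.extended:
                if n_iter % 10 == 1:  # re-estimate source kurtosis signs
                    m2 = (U**2).mean(axis=1)
                    m4 = (U**4).mean(axis=1)
                    signs = np.sign(m4 / m2**2 - 3.0)
                    signs[signs == 0] = 1.0
                grad = (
                    np.eye(K)
                    - (signs[:, None] * np.tanh(U)) @ U.T / n_fit
                    - U @ U.T / n_fit
                ) @ W
            else:
                Y = 1.0 / (1.0 + np.exp(-U))
                grad = (np.eye(K) + (1.0 - 2.0 * Y) @ U.T / n_fit) @ W
            delta = lr * grad
            dnorm = np.linalg.norm(delta)
            if not np.isfinite(dnorm):
                # diverged: restart colder
                W = np.eye(K) + 1e-3 * rng.standard_normal((K, K))
                lr *= 0.5
                prev_delta = None
                continue
            if prev_delta is not None:
                cosang = (delta * prev_delta).sum() / (
                    np.linalg.norm(delta) * np.linalg.norm(prev_delta) + 1e-300
                )
                if cosang < 0.5:  # oscillation: anneal
                    lr *= self.anneal
            W = W + delta
            prev_delta = delta
            if dnorm < self.tol * max(np.linalg.norm(W), 1.0):
                converged = True
                break

        unmixing = W @ whitening  # K x channels
        A = unmixing @ D
        # fix scale (unit activation variance) and sign (positive skewness)
        sd = A.std(axis=1)
        sd[sd == 0] = 1.0
        unmixing = unmixing / sd[:, None]
        A = A / sd[:, None]
        skew = ((A - A.mean(axis=1, keepdims=True)) ** 3).mean(axis=1)
        flip = np.where(skew != 0, np.sign(skew), np.sign(A[np.arange(len(A)), np.abs(A).argmax(axis=1)]))
        flip[flip == 0] = 1.0
        unmixing = unmixing * flip[:, None]
        A = A * flip[:, None]

        self.unmixing_ = unmixing
        self.mixing_ = np.linalg.pinv(unmixing)
        self.whitening_ = whitening
        self.activations_ = A
        self.components_ = unmixing  # sklearn-style alias
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = n_chan
        return self

    def transform(self, X: ArrayLike) -> NDArray:
        """Project new data through the frozen unmixing.

        Each channel of ``X`` (n_samples, n_channels) is demeaned with its
        *own* mean (the held-out data's offsets, never the training means)
        before projection; no re-estimation takes place.
        """
        check_is_fitted(self, "unmixing_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must be (n_samples, {self.n_features_in_}); got {X.shape}"
            )
        D, _ = demean(X.T, axis=-1)
        return (self.unmixing_ @ D).T

    def fit_transform(self, X: ArrayLike, y=None) -> NDArray:
        return self.fit(X).activations_.T

    # ------------------------------------------------------------------
    def to_model(self, channel_names: list[str] | None = None, modality: str = "eeg") -> MixingModel:
        check_is_fitted(self, "unmixing_")
        return MixingModel(
            mixing=self.mixing_,
            unmixing=self.unmixing_,
            sphering=self.whitening_,
            activations=self.activations_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            seed=self.random_state,
            channel_names=channel_names,
            modality=modality,
        )


# ----------------------------------------------------------------------
# thin functional wrappers (module-level surface)

def fit_infomax(
    data: ArrayLike,
    n_components: int | None = None,
    learning_rate: float = 0.2,
    max_iter: int = 512,
    tol: float = 1e-7,
    seed: int | None = None,
    extended: bool = False,
) -> MixingModel:
    """Fit Infomax ICA on ``data`` given as channels x samples.

    Functional wrapper over :class:`InfomaxICA` using the channels-first
    layout natural for EEG matrices.
    """
    est = InfomaxICA(
        n_components=n_components,
        learning_rate=learning_rate,
        max_iter=max_iter,
        tol=tol,
        extended=extended,
        random_state=seed,
    )
    est.fit(np.asarray(data, dtype=float).T)
    return est.to_model()


def project_components(model: MixingModel, new_data: ArrayLike) -> NDArray:
    """Activations of ``new_data`` (channels x samples) under a frozen model.

    The projection is ``unmixing @ demean(new_data)`` — the model is never
    refit, which is what keeps held-out trials out of every fitted object.
    """
    new_data = np.asarray(new_data, dtype=float)
    if new_data.shape[0] != model.n_channels:
        raise ValueError(
            f"channel mismatch: model has {model.n_channels} channels, "
            f"data has {new_data.shape[0]}"
        )
    D, _ = demean(new_data, axis=-1)
    return model.unmixing @ D
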