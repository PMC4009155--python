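"""Quantized kernel least-mean-square (Q-KLMS) regression in the RKHS of a
composite multiscale kernel.

The model keeps a dictionary of center samples ``c_n`` and an
outputs-by-centers coefficient matrix ``a``; its prediction on an input ``u``
is ``a @ [kappa(c_1, u), ..., kappa(c_N, u)]``.  On each update the prediction
error ``e = d - y`` either adjusts the coefficient column of the nearest
center (if the RKHS distance to it is at most the quantization size
``eps_q``) or spawns a new center with column ``eta * e``.  With ``eps_q = 0``
repeated inputs merge onto one center and the algorithm matches plain KLMS on
distinct inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import EmptyModelError
from .kernels import CompositeKernelSpec, pairwise_kernel, rkhs_distance
from .samples import MultiscaleSample

__all__ = ["QKLMSModel", "LearningTrace", "train"]


@dataclass
class LearningTrace:
    """Per-update history of a training run."""

    errors: np.ndarray       # (steps, n_outputs) pre-update prediction errors
    dict_size: np.ndarray    # (steps,) dictionary size after each update
    epoch: np.ndarray        # (steps,) 0-based epoch index of each update

    def epoch_mse(self) -> np.ndarray:
        """Mean squared prediction error per epoch."""
        n_epochs = int(self.epoch.max()) + 1 if self.epoch.size else 0
        sq = np.sum(self.errors**2, axis=1)
        return np.array([sq[self.epoch == e].mean() for e in range(n_epochs)])


class QKLMSModel:
    """Online Q-KLMS learner with a shared dictionary across outputs.

    Parameters
    ----------
    kernel_spec
        Fully resolved composite kernel (kernel sizes set).
    n_outputs
        Number of simultaneously learned output channels ``M``.
    learning_rate
        LMS step size ``eta``; stable below ``1 / max self-similarity``.
    quantization_size
        RKHS-distance threshold ``eps_q`` below which an input is merged onto
        its nearest center.  ``0`` merges exact repeats only.
    """

    def __init__(
        self,
        kernel_spec: CompositeKernelSpec,
        n_outputs: int,
        learning_rate: float = 0.5,
        quantization_size: float = 0.0,
    ) -> None:
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if quantization_size < 0:
            raise ValueError("quantization_size must be non-negative")
        self.kernel_spec = kernel_spec
        self.n_outputs = int(n_outputs)
        self.learning_rate = float(learning_rate)
        self.quantization_size = float(quantization_size)
        self.centers: list[MultiscaleSample] = []
        # coefficient columns and self-similarity cache live in preallocated
        # arrays (doubling growth) so per-step access is O(1) numpy work
        self._coef_arr = np.zeros((self.n_outputs, 8))
        self._self_sim_arr = np.zeros(8)
        self._n = 0
        self.center_sources: list[int | None] = []  # training-set index, if any

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_centers(self) -> int:
        return self._n

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient matrix of shape (n_outputs, n_centers) (a view)."""
        return self._coef_arr[:, : self._n]

    @property
    def self_similarities(self) -> np.ndarray:
        return self._self_sim_arr[: self._n]

    def _append_center(
        self, u: MultiscaleSample, column: np.ndarray, self_sim: float
    ) -> None:
        if self._n == self._coef_arr.shape[1]:
            cap = 2 * self._n
            self._coef_arr = np.concatenate(
                [self._coef_arr, np.zeros((self.n_outputs, cap - self._n))], axis=1
            )
            self._self_sim_arr = np.concatenate(
                [self._self_sim_arr, np.zeros(cap - self._n)]
            )
        self.centers.append(u)
        self._coef_arr[:, self._n] = column
        self._self_sim_arr[self._n] = self_sim
        self._n += 1
        self.center_sources.append(None)

    def copy(self) -> "QKLMSModel":
        """Deep-enough copy: shares immutable center samples, copies
        coefficients and caches."""
        m = QKLMSModel(
            self.kernel_spec, self.n_outputs, self.learning_rate, self.quantization_size
        )
        m.centers = list(self.centers)
        m._coef_arr = self._coef_arr.copy()
        m._self_sim_arr = self._self_sim_arr.copy()
        m._n = self._n
        m.center_sources = list(self.center_sources)
        return m

    # -- kernel evaluation -------------------------------------------------
    def kernel_vector(self, u: MultiscaleSample) -> np.ndarray:
        """``[kappa(c_n, u)]`` over the dictionary."""
        if not self.centers:
            return np.zeros(0)
        return pairwise_kernel(self.centers, [u], self.kernel_spec)[:, 0]

    def _self_similarity(self, u: MultiscaleSample) -> float:
        return float(pairwise_kernel([u], None, self.kernel_spec)[0, 0])

    # -- core operations ----------------------------------------------------
    def predict(self, u: MultiscaleSample, kvec: np.ndarray | None = None) -> np.ndarray:
        """Model output for one sample; zero vector for an empty dictionary."""
        if not self.centers:
            return np.zeros(self.n_outputs)
        if kvec is None:
            kvec = self.kernel_vector(u)
        return self.coefficients @ kvec

    def nearest_center(
        self, u: MultiscaleSample, kvec: np.ndarray | None = None,
        k_uu: float | None = None,
    ) -> tuple[int, float]:
        """Index and RKHS distance of the closest dictionary center.

        Ties are broken by the lowest center index (deterministic replay).
        """
        if not self.centers:
            raise EmptyModelError("model has no centers")
        if kvec is None:
            kvec = self.kernel_vector(u)
        if k_uu is None:
            k_uu = self._self_similarity(u)
        d2 = np.maximum(self.self_similarities + k_uu - 2.0 * kvec, 0.0)
        idx = int(np.argmin(d2))  # argmin returns the first minimum
        return idx, float(np.sqrt(d2[idx]))

    def update(
        self,
        u: MultiscaleSample,
        d: Sequence[float],
        kvec: np.ndarray | None = None,
        k_uu: float | None = None,
    ) -> np.ndarray:
        """One Q-KLMS step on the pair ``(u, d)``; returns the pre-update
        prediction error ``e = d - predict(u)``."""
        d = np.asarray(d, dtype=float)
        if d.shape != (self.n_outputs,):
            raise ValueError(f"target must have shape ({self.n_outputs},)")
        if not np.all(np.isfinite(d)):
            raise ValueError("target contains non-finite values")
        if kvec is None:
            kvec = self.kernel_vector(u)
        e = d - self.predict(u, kvec=kvec)
        if self._n:
            if k_uu is None:
                k_uu = self._self_similarity(u)
            idx, dist = self.nearest_center(u, kvec=kvec, k_uu=k_uu)
            if dist <= self.quantization_size:
                self._coef_arr[:, idx] += self.learning_rate * e
                return e
        self._append_center(
            u,
            self.learning_rate * e,
            self._self_similarity(u) if k_uu is None else float(k_uu),
        )
        return e


def train(
    model: QKLMSModel,
    inputs: Sequence[MultiscaleSample],
    targets: np.ndarray,
    epochs: int = 1,
    gram: np.ndarray | None = None,
    cross_gram: np.ndarray | None = None,
) -> LearningTrace:
    """Sequential Q-KLMS training over a dataset, repeated for ``epochs``.

    Inputs are presented in data order within every epoch (no shuffling), so
    runs replay exactly.  Because later epochs revisit the same samples, with
    ``eps_q = 0`` the dictionary stops growing after the first epoch and the
    coefficients keep converging, which is why multiple passes are useful.

    All pairwise kernel values among ``inputs`` (and between ``inputs`` and
    any pre-existing centers) are evaluated once up front, which makes the
    per-step cost a vector operation.  ``gram``/``cross_gram`` allow callers
    that already computed those matrices to pass them in; the values must be
    exactly the ones :func:`spikefield.kernels.pairwise_kernel` would return.
    """
    inputs = list(inputs)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[0] != len(inputs):
        raise ValueError("inputs and targets must have equal length")
    if len(inputs) == 0:
        raise ValueError("training set is empty")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")

    if gram is None:
        gram = pairwise_kernel(inputs, None, model.kernel_spec)
    if cross_gram is None and model.centers:
        cross_gram = pairwise_kernel(model.centers, inputs, model.kernel_spec)

    n_prior = model.n_centers
    # input index backing each center added during this call (preallocated so
    # the per-step kernel lookup is a single fancy index)
    new_src = np.empty(len(inputs), dtype=int)
    n_new = 0

    errors, sizes, epoch_ix = [], [], []
    for ep in range(epochs):
        for j in range(len(inputs)):
            kvec = np.empty(n_prior + n_new)
            if n_prior:
                kvec[:n_prior] = cross_gram[:, j]
            if n_new:
                kvec[n_prior:] = gram[new_src[:n_new], j]
            k_uu = gram[j, j]
            before = model.n_centers
            e = model.update(inputs[j], targets[j], kvec=kvec, k_uu=k_uu)
            if model.n_centers > before:
                model.center_sources[-1] = j
                new_src[n_new] = j
                n_new += 1
            errors.append(e)
            sizes.append(model.n_centers)
            epoch_ix.append(ep)
    return LearningTrace(
        errors=np.asarray(errors),
        dict_size=np.asarray(sizes, dtype=int),
        epoch=np.asarray(epoch_ix, dtype=int),
    )
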