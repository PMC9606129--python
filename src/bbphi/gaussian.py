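"""Gaussian integrated-information engine (IIT 2.0, mismatched decoding).

This module implements the whole-system quantities for a stationary Gaussian
approximation of a multichannel time series:

* lagged second-order model estimation (:func:`estimate_lagged_model`),
* past–present mutual information I(X(t-τ); X(t)) (:func:`mutual_information`),
* the mismatched-decoding information Ĩ(β) for a bipartition
  (:func:`mismatched_information`),
* integrated information Φ* = I − max_β Ĩ(β) (:func:`phi_star`),
* and the exhaustive minimum-information-partition search
  (:func:`mip_search`).

Φ* quantifies how much past→present information is lost when the decoder is
forced to treat the two blocks of a bipartition as independent channels; the
MIP is the bipartition across which that loss is smallest — the system's
weakest informational link.  All quantities are reported in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _batch
from ._batch import BETA_HI, BETA_LO, SingularModelError

__all__ = [
    "Bipartition",
    "LaggedGaussianModel",
    "PhiResult",
    "SingularModelError",
    "enumerate_bipartitions",
    "estimate_lagged_model",
    "mutual_information",
    "mismatched_information",
    "phi_star",
    "mip_search",
    "DEFAULT_RIDGE_SCALE",
]

#: relative ridge: this times the mean diagonal variance is added to the
#: past/present covariance diagonals when no explicit ridge is given.
DEFAULT_RIDGE_SCALE = 1e-8


@dataclass(frozen=True, order=True)
class Bipartition:
    """An unordered two-block split of node indices, held in canonical form.

    ``block_a`` is the block containing the smallest index; both blocks are
    sorted tuples.  Construct via :meth:`from_blocks` to enforce this.
    """

    block_a: tuple[int, ...]
    block_b: tuple[int, ...]

    @classmethod
    def from_blocks(cls, block_a: Sequence[int], block_b: Sequence[int]) -> "Bipartition":
        a = tuple(sorted(set(int(i) for i in block_a)))
        b = tuple(sorted(set(int(i) for i in block_b)))
        if not a or not b:
            raise ValueError("both blocks of a bipartition must be nonempty")
        if set(a) & set(b):
            raise ValueError("bipartition blocks must be disjoint")
        if b[0] < a[0]:
            a, b = b, a
        return cls(a, b)

    def __post_init__(self):
        if self.block_a and self.block_b and self.block_b[0] < self.block_a[0]:
            raise ValueError("not canonical: block_a must contain the smallest index")

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(sorted(self.block_a + self.block_b))

    @property
    def n(self) -> int:
        return len(self.block_a) + len(self.block_b)

    def key(self, labels: Optional[Sequence[str]] = None) -> str:
        """Human-readable cut key, smaller block first (e.g. ``"Oz | rest"``).

        With channel ``labels`` the key names the smaller block, matching the
        "{Oz}-cut" style used when reporting MIP-cut frequencies.
        """
        small, big = self.block_a, self.block_b
        if len(big) < len(small) or (len(big) == len(small) and big < small):
            small, big = big, small
        if labels is None:
            return "+".join(str(i) for i in small)
        return "+".join(labels[i] for i in small)


def enumerate_bipartitions(nodes: Sequence[int] | int) -> list[Bipartition]:
    """All unordered bipartitions of a node set, in canonical order.

    For n nodes there are 2^(n-1) − 1 of them; the listing is sorted by
    ``block_a`` lexicographically (the deterministic tie-break order used by
    :func:`mip_search`).
    """
    if isinstance(nodes, (int, np.integer)):
        nodes = range(int(nodes))
    nodes = sorted(int(i) for i in nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes to bipartition")
    parts = []
    rest = nodes[1:]
    for mask in range(1, 2 ** (n - 1)):
        block_b = tuple(rest[i] for i in range(n - 1) if mask >> i & 1)
        block_a = tuple(i for i in nodes if i not in block_b)
        parts.append(Bipartition(block_a, block_b))
    parts.sort()
    return parts


@dataclass
class LaggedGaussianModel:
    """Second-order statistics of the lagged pair (X(t−τ), X(t)).

    ``cross_cov[i, j]`` is Cov[x_i(t−τ), x_j(t)].  This object is the sole
    input to every Φ computation; restricting it to a channel subset (for the
    complex search) is plain sub-block slicing.
    """

    labels: tuple[str, ...]
    tau: int
    cov_past: np.ndarray
    cov_present: np.ndarray
    cross_cov: np.ndarray
    n_samples: int = 0
    ridge: float = 0.0

    def __post_init__(self):
        self.labels = tuple(self.labels)
        n = len(self.labels)
        for name in ("cov_past", "cov_present", "cross_cov"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n} to match the labels")
            setattr(self, name, m)
        for name in ("cov_past", "cov_present"):
            m = getattr(self, name)
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            setattr(self, name, 0.5 * (m + m.T))
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    @property
    def n(self) -> int:
        return len(self.labels)

    def joint(self) -> np.ndarray:
        """The 2n×2n covariance of the stacked vector (X(t−τ), X(t))."""
        return _batch.joint_covariance(
            self.cov_past[None], self.cov_present[None], self.cross_cov.T[None]
        )[0]

    def restrict(self, subset: Sequence[int]) -> "LaggedGaussianModel":
        """The model induced on a channel subset (sub-blocks of all matrices)."""
        idx = sorted(int(i) for i in subset)
        if len(idx) < 1 or len(set(idx)) != len(idx) or idx[-1] >= self.n:
            raise ValueError("subset must be distinct valid channel indices")
        ix = np.ix_(idx, idx)
        return LaggedGaussianModel(
            labels=tuple(self.labels[i] for i in idx),
            tau=self.tau,
            cov_past=self.cov_past[ix],
            cov_present=self.cov_present[ix],
            cross_cov=self.cross_cov[ix],
            n_samples=self.n_samples,
            ridge=self.ridge,
        )


@dataclass
class PhiResult:
    """Outcome of a MIP search for one model: Φ_MIP, the cut, I, and β*."""

    phi_mip: float
    mip: Bipartition
    mutual_info: float
    beta_opt: float
    per_partition: Optional[pd.DataFrame] = field(default=None, repr=False)


def estimate_lagged_model(
    window: np.ndarray,
    tau: int,
    ridge: Optional[float] = None,
    labels: Optional[Sequence[str]] = None,
) -> LaggedGaussianModel:
    """Estimate the lagged Gaussian model from a frames×channels window.

    Pairs (x(t−τ), x(t)) for t = τ…T−1 are formed, each side is mean-centred
    per channel, and maximum-likelihood covariances (divide by the pair
    count) are taken.  ``ridge`` (absolute) is added to both covariance
    diagonals; when None, ``DEFAULT_RIDGE_SCALE`` × mean diagonal variance is
    used.  A channel that is constant over the window is an error when the
    effective ridge is zero, and a warning otherwise.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] < 2:
        raise ValueError("window must be a frames x channels matrix with >= 2 channels")
    t_len, n = window.shape
    tau = int(tau)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if t_len < tau + 2:
        raise ValueError(
            f"window of {t_len} frames is too short for tau={tau}; need >= tau+2"
        )
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n))
    labels = tuple(labels)
    if len(labels) != n:
        raise ValueError("labels must match the number of channels")

    past = window[: t_len - tau]
    present = window[tau:]
    x = past - past.mean(axis=0)
    y = present - present.mean(axis=0)
    n_samples = t_len - tau
    cov_past = x.T @ x / n_samples
    cov_present = y.T @ y / n_samples
    cross_cov = x.T @ y / n_samples  # Cov[x(t−τ), x(t)]

    diag = 0.5 * (np.diag(cov_past) + np.diag(cov_present))
    if ridge is None:
        ridge_val = DEFAULT_RIDGE_SCALE * float(diag.mean())
    else:
        ridge_val = float(ridge)
    span = window.max(axis=0) - window.min(axis=0)
    flat = np.where((span == 0.0) | (diag <= 0.0))[0]
    if flat.size:
        names = ", ".join(labels[i] for i in flat)
        if ridge_val <= 0.0:
            raise ValueError(
                f"channel(s) {names} are constant over the window and no ridge "
                "regularisation is in effect"
            )
        warnings.warn(
            f"channel(s) {names} are constant over the window; covariances are "
            "ridge-regularised and Phi values will be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    cov_past = cov_past + ridge_val * np.eye(n)
    cov_present = cov_present + ridge_val * np.eye(n)
    return LaggedGaussianModel(
        labels=labels,
        tau=tau,
        cov_past=cov_past,
        cov_present=cov_present,
        cross_cov=cross_cov,
        n_samples=n_samples,
        ridge=ridge_val,
    )


def _stacks(model: LaggedGaussianModel):
    sxx = model.cov_past[None]
    syy = model.cov_present[None]
    syx = model.cross_cov.T[None]  # Cov[X(t), X(t−τ)]
    return sxx, syy, syx


def mutual_information(model: LaggedGaussianModel) -> float:
    """I(X(t−τ); X(t)) = ½ ln(|Σ_past||Σ_present| / |Σ_joint|), in nats."""
    sxx, syy, syx = _stacks(model)
    return float(_batch.mutual_information_batch(sxx, syy, syx)[0])


def _partition_mask(model: LaggedGaussianModel, partition: Bipartition) -> np.ndarray:
    if partition.nodes != tuple(range(model.n)):
        raise ValueError(
            f"partition over nodes {partition.nodes} does not cover the model's "
            f"{model.n} channels"
        )
    return _batch.block_mask(model.n, partition.block_b)[None]


def mismatched_information(
    model: LaggedGaussianModel, partition: Bipartition, beta: float
) -> float:
    """Ĩ(β): information through the partition-factorised Gaussian decoder.

    The decoder q(x(t)|x(t−τ)) = Π_b p(x_b(t)|x_b(t−τ)) ignores every
    cross-block dependency; Ĩ(β) ≤ I(X(t−τ); X(t)) for all β > 0.
    """
    if not beta > 0:
        raise ValueError("beta must be > 0")
    sxx, syy, syx = _stacks(model)
    pre = _batch.precompute_mismatch(sxx, syy, syx, _partition_mask(model, partition))
    return float(_batch.mismatched_information_batch(pre, np.array([beta]))[0])


def phi_star(model: LaggedGaussianModel, partition: Bipartition) -> tuple[float, float]:
    """Integrated information Φ*(π) = I − max_β Ĩ(β) and the maximising β.

    β is maximised over (1e−6, 32] by golden-section search; Φ* is
    non-negative up to that numerical tolerance and never exceeds I.
    """
    sxx, syy, syx = _stacks(model)
    mi = _batch.mutual_information_batch(sxx, syy, syx)[0]
    pre = _batch.precompute_mismatch(sxx, syy, syx, _partition_mask(model, partition))
    beta_opt, istar = _batch.maximize_mismatched(pre)
    return float(mi - istar[0]), float(beta_opt[0])


def mip_search(model: LaggedGaussianModel, keep_partitions: bool = False) -> PhiResult:
    """Exhaustive minimum-information-partition search over all bipartitions.

    Enumerates the 2^(n−1) − 1 unordered bipartitions, computes Φ*(π) for
    each (β line-searches run vectorised across partitions) and returns the
    minimiser; ties go to the canonically first partition.  Set
    ``keep_partitions`` to attach the full Φ*(π) table.
    """
    n = model.n
    if n < 2:
        raise ValueError("MIP search needs at least 2 channels")
    partitions = enumerate_bipartitions(n)
    sxx, syy, syx = _stacks(model)
    mi = float(_batch.mutual_information_batch(sxx, syy, syx)[0])
    masks = np.stack([_batch.block_mask(n, p.block_b) for p in partitions])
    m = len(partitions)
    pre = _batch.precompute_mismatch(
        np.broadcast_to(sxx, (m, n, n)),
        np.broadcast_to(syy, (m, n, n)),
        np.broadcast_to(syx, (m, n, n)),
        masks,
    )
    beta_opt, istar = _batch.maximize_mismatched(pre)
    phis = mi - istar
    best = int(np.argmin(phis))
    table = None
    if keep_partitions:
        table = pd.DataFrame(
            {
                "partition": partitions,
                "key": [p.key(model.labels) for p in partitions],
                "phi": phis,
                "beta_opt": beta_opt,
            }
        )
    return PhiResult(
        phi_mip=float(phis[best]),
        mip=partitions[best],
        mutual_info=mi,
        beta_opt=float(beta_opt[best]),
        per_partition=table,
    )
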