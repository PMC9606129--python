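"""Stacked Gaussian information primitives.

Everything Φ-related in this package reduces to the same small computation
repeated many times: given the second-order statistics of a lagged Gaussian
pair (X(t-τ), X(t)) restricted to some channel subset, and a bipartition of
that subset, evaluate the mismatched-decoding information Ĩ(β) and maximise
it over β.  A single analysis window touches ~10^3 (subset, partition)
combinations, so these routines operate on stacks of m independent problems
at once (arrays of shape (m, k, k)) and the β line-search is a vectorised
golden-section that advances all m problems per iteration.

Conventions
-----------
``sxx``  covariance of the past state X(t-τ)            (m, k, k)
``syy``  covariance of the present state X(t)           (m, k, k)
``syx``  cross covariance Cov[X(t), X(t-τ)]             (m, k, k)
``w``    same-block indicator: w[i, j] = 1 iff channels i and j fall in the
         same block of the bipartition                  (m, k, k)

All information quantities are in nats.

The mismatched decoder for a bipartition factorises the true conditional
p(y|x) over the blocks: q(y|x) = Π_b p(y_b | x_b).  For Gaussians every
block factor is the linear regression of y_b on x_b, so q is itself Gaussian
with a block-diagonal regression matrix A' and block-diagonal residual
covariance Σ'.  Ĩ(β) = E_p[ln( q(y|x)^β / E_{x'}[q(y|x')^β] )] is then a
closed-form Gaussian integral; the derivation is standard completion of the
square and is exercised against a quadrature/Monte-Carlo oracle in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "block_mask",
    "joint_covariance",
    "mutual_information_batch",
    "MismatchPrecompute",
    "precompute_mismatch",
    "mismatched_information_batch",
    "maximize_mismatched",
    "BETA_LO",
    "BETA_HI",
]

# β search bracket: Ĩ(β) -> 0 as β -> 0+, and the maximiser sits near 1 for
# near-matched decoders; 32 is a generous upper edge for strongly mismatched
# low-dimensional problems.
BETA_LO = 1e-6
BETA_HI = 32.0
_GOLDEN_ITERS = 52  # bracket width 32 * 0.618^52 < 1e-10


class SingularModelError(np.linalg.LinAlgError):
    """A covariance block is numerically singular; increase the ridge."""


def block_mask(n: int, block_b) -> np.ndarray:
    """Boolean (n, n) same-block mask for the bipartition (complement, block_b)."""
    in_b = np.zeros(n, dtype=bool)
    in_b[list(block_b)] = True
    same = in_b[:, None] == in_b[None, :]
    return same


def joint_covariance(sxx: np.ndarray, syy: np.ndarray, syx: np.ndarray) -> np.ndarray:
    """Assemble the (…, 2k, 2k) covariance of the stacked vector (x, y)."""
    sxy = np.swapaxes(syx, -1, -2)
    top = np.concatenate([sxx, sxy], axis=-1)
    bot = np.concatenate([syx, syy], axis=-1)
    return np.concatenate([top, bot], axis=-2)


def _slogdet_pd(a: np.ndarray, what: str) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(a)
    if np.any(sign <= 0):
        raise SingularModelError(
            f"{what} is not positive definite; add (or increase) the ridge "
            "regularisation on the covariance diagonals"
        )
    return logdet


def mutual_information_batch(sxx, syy, syx) -> np.ndarray:
    """I(X(t-τ); X(t)) = ½ ln( |Σxx||Σyy| / |Σjoint| ) per stacked model."""
    ld_x = _slogdet_pd(sxx, "past covariance")
    ld_y = _slogdet_pd(syy, "present covariance")
    ld_j = _slogdet_pd(joint_covariance(sxx, syy, syx), "joint covariance")
    return 0.5 * (ld_x + ld_y - ld_j)


class MismatchPrecompute:
    """β-independent matrices for a stack of (model, bipartition) problems.

    Evaluating Ĩ(β) afterwards costs one batched solve and one batched
    slogdet per β, which is what makes the golden-section search cheap.
    """

    __slots__ = ("m", "isxx", "ld_sxx", "c0", "mmat", "pmat", "t1")

    def __init__(self, m, isxx, ld_sxx, c0, mmat, pmat, t1):
        self.m = m
        self.isxx = isxx
        self.ld_sxx = ld_sxx
        self.c0 = c0
        self.mmat = mmat
        self.pmat = pmat
        self.t1 = t1


def precompute_mismatch(sxx, syy, syx, w) -> MismatchPrecompute:
    """Precompute everything β-independent for stacked Ĩ(β) evaluation.

    The block-restricted regression is built with a masking trick: for a
    same-block mask W, (Σ∘W) is block-diagonal after simultaneous row/column
    permutation, so (Σyx∘W)(Σxx∘W)^{-1} is exactly the direct sum of the
    per-block regressions y_b ~ x_b, without any per-block slicing.
    """
    sxx = np.asarray(sxx, dtype=float)
    syy = np.asarray(syy, dtype=float)
    syx = np.asarray(syx, dtype=float)
    w = np.asarray(w, dtype=float)
    m = sxx.shape[0]

    sxy = np.swapaxes(syx, -1, -2)
    isxx = np.linalg.inv(sxx)
    ld_sxx = _slogdet_pd(sxx, "past covariance")

    sxx_w = sxx * w
    syx_w = syx * w
    # A' = (Σyx∘W)(Σxx∘W)^{-1}: block-diagonal mismatched regression matrix.
    try:
        a = np.linalg.solve(np.swapaxes(sxx_w, -1, -2), np.swapaxes(syx_w, -1, -2))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularModelError(
            "a block of the past covariance is singular; add ridge regularisation"
        ) from exc
    a = np.swapaxes(a, -1, -2)
    # Σ' = block-diagonal residual covariance of the per-block regressions.
    scond = syy * w - a @ np.swapaxes(syx_w, -1, -2)
    iscond = np.linalg.inv(scond)
    _slogdet_pd(scond, "block-conditional covariance")

    # C = E[(y - A'x)(y - A'x)^T] under the *true* joint distribution.
    c = syy - syx @ np.swapaxes(a, -1, -2) - a @ sxy + a @ sxx @ np.swapaxes(a, -1, -2)
    c0 = np.einsum("mij,mji->m", iscond, c)

    g = iscond @ a
    mmat = np.swapaxes(a, -1, -2) @ g  # A'^T Σ'^{-1} A'
    pmat = np.swapaxes(g, -1, -2) @ syy @ g
    t1 = np.einsum("mij,mji->m", iscond, syy)
    return MismatchPrecompute(m, isxx, ld_sxx, c0, mmat, pmat, t1)


def mismatched_information_batch(pre: MismatchPrecompute, beta: np.ndarray) -> np.ndarray:
    """Closed-form Ĩ(β) for the stacked problems; ``beta`` has shape (m,)."""
    beta = np.asarray(beta, dtype=float)
    q = pre.isxx + beta[:, None, None] * pre.mmat
    sign, ld_q = np.linalg.slogdet(q)
    if np.any(sign <= 0):  # pragma: no cover - Q = Σxx^{-1} + β·PSD is PD
        raise SingularModelError("β-normaliser matrix lost positive definiteness")
    tr_qp = np.trace(np.linalg.solve(q, pre.pmat), axis1=-2, axis2=-1)
    return (
        -0.5 * beta * pre.c0
        + 0.5 * (ld_q + pre.ld_sxx)
        + 0.5 * (beta * pre.t1 - beta * beta * tr_qp)
    )


def maximize_mismatched(
    pre: MismatchPrecompute,
    beta_lo: float = BETA_LO,
    beta_hi: float = BETA_HI,
    iters: int = _GOLDEN_ITERS,
):
    """Vectorised golden-section maximisation of Ĩ(β) over (beta_lo, beta_hi].

    Ĩ(β) is smooth and unimodal for these Gaussian decoders, so a fixed
    iteration count shrinks every bracket below 1e-10 deterministically.
    Returns (beta_opt, istar), each of shape (m,).
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    m = pre.m
    a = np.full(m, beta_lo)
    b = np.full(m, beta_hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = mismatched_information_batch(pre, c)
    fd = mismatched_information_batch(pre, d)
    for _ in range(iters):
        left = fc > fd  # per-problem: maximum lies in [a, d]
        c_old, d_old, fc_old, fd_old = c, d, fc, fd
        b = np.where(left, d_old, b)
        a = np.where(left, a, c_old)
        c = np.where(left, b - invphi * (b - a), d_old)
        d = np.where(left, c_old, a + invphi * (b - a))
        # exactly one interior point per problem is fresh this iteration
        f_new = mismatched_information_batch(pre, np.where(left, c, d))
        fc = np.where(left, f_new, fd_old)
        fd = np.where(left, fc_old, f_new)
    beta_opt = 0.5 * (a + b)
    istar = mismatched_information_batch(pre, beta_opt)
    return beta_opt, istar
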