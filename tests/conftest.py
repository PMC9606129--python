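"""Shared fixtures: analytic VAR(1) models and hand-built subject series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import solve_discrete_lyapunov

from bbphi.gaussian import LaggedGaussianModel
from bbphi.pipeline import SubjectSeries, WindowConfig


def stable_var_coefficients(rng: np.random.Generator, n: int, radius: float = 0.9) -> np.ndarray:
    """A random VAR(1) coefficient matrix rescaled to the given spectral radius."""
    a = rng.standard_normal((n, n)) * 0.5
    rho = np.max(np.abs(np.linalg.eigvals(a)))
    if rho > 0:
        a *= rng.uniform(0.3, radius) / rho
    return a


def var1_model(a: np.ndarray, noise: np.ndarray | None = None, tau: int = 1,
               labels=None) -> LaggedGaussianModel:
    """Exact lagged Gaussian model of a stationary VAR(1) x(t)=A·x(t−1)+ε.

    The stationary covariance Σ solves Σ = AΣAᵀ + Q; the lag-τ cross
    covariance Cov[x(t−τ), x(t)] is Σ·(A^τ)ᵀ.  This analytic route is the
    oracle side used against the sample-estimation route.
    """
    n = a.shape[0]
    q = np.eye(n) if noise is None else noise
    sigma = solve_discrete_lyapunov(a, q)
    sigma = 0.5 * (sigma + sigma.T)
    cross = sigma @ np.linalg.matrix_power(a, tau).T
    return LaggedGaussianModel(
        labels=labels or tuple(f"n{i}" for i in range(n)),
        tau=tau,
        cov_past=sigma,
        cov_present=sigma.copy(),
        cross_cov=cross,
        n_samples=0,
        ridge=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_series(
    subject_id: str,
    condition: str,
    phi: np.ndarray,
    sum_main: np.ndarray | None = None,
    cuts: list[str] | None = None,
    max_mains: list[str] | None = None,
    n_steps: int | None = None,
) -> SubjectSeries:
    """Assemble a SubjectSeries directly from value arrays (no Φ computation)."""
    phi = np.asarray(phi, float)
    n = phi.size
    total = n_steps or n
    third = total // 3
    steps = np.arange(n)
    phases = np.where(steps < third, "pre", np.where(steps < 2 * third, "stim", "post"))
    table = pd.DataFrame(
        {
            "step": steps,
            "phase": phases,
            "missing": False,
            "phi_mip": phi,
            "mip_cut": cuts if cuts is not None else [""] * n,
            "mutual_info": phi * 2,
            "sum_main_phi": sum_main if sum_main is not None else phi,
            "n_complexes": 1,
            "n_main": 1,
            "max_main_subset": max_mains if max_mains is not None else [""] * n,
            "max_main_phi": phi,
        }
    )
    return SubjectSeries(
        subject_id=subject_id, condition=condition, config=WindowConfig(), table=table
    )
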