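"""Ground-truth ensembles and noisy synthetic observables.

Stands in for undeposited experimental data: picks a sparse truth ensemble
from a conformer pool with a prescribed bound-state population, then emits
the observables the analysis consumes -- a noisy SAXS profile, noisy domain
correlation times, and per-residue relaxation records -- with the same noise
structure good beamline/NMR data would have.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool import BOUND, ValidationError
from .relax import (DiffusionFit, DomainTauExperiment, RelaxationDataset,
                    predict_relaxation)
from .saxs import ScatteringProfile

# noise defaults: ~1% multiplicative SAXS, 5% taus, 2% relaxation rates
DEFAULT_SAXS_A = 0.01
DEFAULT_SAXS_B = 0.001
DEFAULT_TAU_FRAC = 0.05
DEFAULT_RELAX_FRAC = 0.02


@dataclass
class SyntheticTruth:
    """A sparse ground-truth ensemble over a pool."""

    member_indices: np.ndarray
    weights: np.ndarray  # aligned with member_indices, sum to 1
    member_ids: list
    bound_mask: np.ndarray  # which truth members are BOUND
    seed: int
    noise: dict = field(default_factory=dict)

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.bound_mask = np.asarray(self.bound_mask, dtype=bool)
        if np.any(self.weights < 0):
            raise ValidationError("truth weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("truth weights must sum to 1")

    @property
    def k(self):
        return len(self.member_indices)

    def bound_percent(self):
        return float(self.weights[self.bound_mask].sum() * 100.0)

    def dense_weights(self, n_ens):
        w = np.zeros(n_ens)
        w[self.member_indices] = self.weights
        return w

    def to_json(self):
        return {"member_indices": self.member_indices.tolist(),
                "weights": self.weights.tolist(),
                "member_ids": list(self.member_ids),
                "bound_mask": self.bound_mask.tolist(),
                "seed": self.seed, "noise": self.noise}

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


def make_truth(pool, k, bound_population, seed, tol=0.5):
    """Select ``k`` members and Dirichlet weights with a fixed bound share.

    The bound-labeled weight sum equals ``bound_population``/100 within
    ``tol`` percentage points (exactly, by block rescaling).
    """
    if not (0.0 <= bound_population <= 100.0):
        raise ValidationError("bound_population must be a percentage")
    rng = np.random.default_rng(seed)
    states = np.array([m.linker_state == BOUND for m in pool])
    n_bound, n_open = int(states.sum()), int((~states).sum())
    p = bound_population / 100.0

    if 0.0 < p < 1.0 and (n_bound == 0 or n_open == 0):
        raise ValidationError(
            f"bound_population={bound_population} infeasible: pool has "
            f"{n_bound} bound / {n_open} open members")
    if p == 1.0 and n_bound == 0:
        raise ValidationError("no bound members available")
    if p == 0.0 and n_open == 0:
        raise ValidationError("no open members available")

    if p == 1.0:
        k_bound = k
    elif p == 0.0:
        k_bound = 0
    else:
        k_bound = int(np.clip(round(k * p), 1, k - 1))
    k_open = k - k_bound
    if k_bound > n_bound or k_open > n_open:
        raise ValidationError("pool too small for the requested truth split")

    idx_bound = rng.choice(np.flatnonzero(states), size=k_bound, replace=False)
    idx_open = rng.choice(np.flatnonzero(~states), size=k_open, replace=False)
    indices = np.concatenate([idx_bound, idx_open]).astype(int)

    # Dirichlet(1) within each block, blocks rescaled to the exact split
    w = np.empty(k)
    if k_bound:
        w[:k_bound] = rng.dirichlet(np.ones(k_bound)) * p
    if k_open:
        w[k_bound:] = rng.dirichlet(np.ones(k_open)) * (1.0 - p)
    order = np.argsort(indices)
    indices, w = indices[order], w[order]
    bound_mask = states[indices]

    truth = SyntheticTruth(indices, w, [pool.members[i].id for i in indices],
                           bound_mask, seed=seed,
                           noise={"saxs_a": DEFAULT_SAXS_A,
                                  "saxs_b": DEFAULT_SAXS_B,
                                  "tau_frac": DEFAULT_TAU_FRAC,
                                  "relax_frac": DEFAULT_RELAX_FRAC})
    if abs(truth.bound_percent() - bound_population) > tol:
        raise ValidationError("bound population constraint violated")
    return truth


def simulate_saxs(truth, pool_profiles, q_grid, a=DEFAULT_SAXS_A,
                  b=DEFAULT_SAXS_B, seed=0):
    """Noisy ensemble SAXS profile.

    I_exp(q) = sum_k w_k I_k(q) + eps(q), eps ~ N(0, sigma(q)^2) with
    sigma(q) = a I(q) + b I(0); the returned profile carries the true sigma.
    """
    profiles = np.asarray(pool_profiles, dtype=float)
    w = truth.dense_weights(profiles.shape[1])
    clean = profiles @ w
    sigma = a * clean + b * clean[0]
    rng = np.random.default_rng(seed)
    noisy = clean + (rng.normal(size=len(clean)) * sigma
                     if (a > 0 or b > 0) else 0.0)
    if np.all(sigma == 0):
        sigma = np.full_like(clean, 1e-12)
    return ScatteringProfile(np.asarray(q_grid, dtype=float), noisy, sigma,
                             meta={"label": "synthetic", "I0": float(clean[0])})


def simulate_domain_taus(truth, pool_taus, frac_sigma=DEFAULT_TAU_FRAC,
                         seed=0):
    """Noisy per-domain correlation times (ensemble averages of the truth)."""
    ta = np.asarray([t.tau_A for t in pool_taus], dtype=float)
    tb = np.asarray([t.tau_B for t in pool_taus], dtype=float)
    w = truth.dense_weights(len(ta))
    mean_a, mean_b = float(ta @ w), float(tb @ w)
    rng = np.random.default_rng(seed)
    if frac_sigma > 0:
        obs_a = mean_a + rng.normal() * frac_sigma * mean_a
        obs_b = mean_b + rng.normal() * frac_sigma * mean_b
        sig_a, sig_b = frac_sigma * mean_a, frac_sigma * mean_b
    else:
        obs_a, obs_b = mean_a, mean_b
        sig_a = sig_b = 1e-9
    return DomainTauExperiment(obs_a, sig_a, obs_b, sig_b)


def simulate_relaxation(diffusion: DiffusionFit, nh_vectors, domain="A",
                        noise_frac=DEFAULT_RELAX_FRAC, field_MHz=800.0,
                        seed=0, first_residue=1):
    """Per-residue T1/T2/NOE records from a diffusion tensor.

    Rates get fractional Gaussian noise ``noise_frac``; NOE noise is additive
    with the same fraction of its magnitude, clipped to the sanity bound.
    """
    nh_vectors = np.asarray(nh_vectors, dtype=float)
    nh_vectors = nh_vectors / np.linalg.norm(nh_vectors, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i, v in enumerate(nh_vectors):
        R1, R2, noe = predict_relaxation(diffusion=diffusion, nh_vector=v,
                                         field_MHz=field_MHz)
        if noise_frac > 0:
            R1 = R1 * (1.0 + noise_frac * rng.normal())
            R2 = R2 * (1.0 + noise_frac * rng.normal())
            noe = noe + noise_frac * abs(noe) * rng.normal()
        noe = min(noe, 1.2)
        rows.append([first_residue + i, domain, 1.0 / R1,
                     noise_frac / R1 if noise_frac else 1e-4 / R1,
                     1.0 / R2,
                     noise_frac / R2 if noise_frac else 1e-4 / R2,
                     noe,
                     noise_frac * abs(noe) if noise_frac else 1e-4])
    table = pd.DataFrame(rows, columns=["residue", "domain", "T1", "sT1",
                                        "T2", "sT2", "NOE", "sNOE"])
    return RelaxationDataset(table, field_MHz, nh_vectors)


def random_nh_vectors(n, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
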