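"""Sparse ensemble selection against joint SAXS + relaxation data.

Builds the stacked design system (sigma-normalized SAXS rows plus two
sqrt(alpha)-scaled correlation-time rows), solves for sparse non-negative
weights with a multi-candidate (beam) orthogonal matching pursuit where every
support is refit by non-negative least squares, selects the ensemble size at
the l-curve knee, and averages near-optimal solutions into populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .relax import DomainTauExperiment

#: weight of the optional sum-to-one constraint row appended at solve time
NORM_ROW_WEIGHT = 1.0e3

#: supports-per-size budget below which the solver enumerates all subsets
#: of that size exactly instead of relying on greedy expansion
EXHAUSTIVE_LIMIT = 2000


class SESError(ValueError):
    pass


@dataclass
class DesignSystem:
    """Stacked linear system chi^2(w) = ||C w - B||^2.

    C has one sigma-normalized row per SAXS point followed by two tau rows
    scaled by sqrt(alpha)/sigma_domain; B holds the matching experimental
    values.  ``row_meta`` tags each row; ``n_q`` is the SAXS row count.
    """

    C: np.ndarray
    B: np.ndarray
    alpha: float
    row_meta: list
    n_q: int
    member_ids: list | None = None
    normalize_weights: bool = True

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.C.shape[0] != len(self.B) or self.C.shape[0] != len(self.row_meta):
            raise SESError("row dimension mismatch")
        if self.alpha < 0:
            raise SESError("alpha must be >= 0")

    @property
    def n_ens(self):
        return self.C.shape[1]

    def chi_parts(self, w):
        """(chi_saxs, chi_relax, chi2_total) for a weight vector.

        chi_saxs uses the normalized convention sqrt(chi2_saxs / n_q);
        chi2_total is the unnormalized objective chi2_saxs + alpha*chi2_relax.
        """
        w = np.asarray(w, dtype=float)
        resid = self.C @ w - self.B
        chi2_saxs = float((resid[:self.n_q] ** 2).sum())
        tau_part = float((resid[self.n_q:] ** 2).sum())
        chi2_relax = tau_part / self.alpha if self.alpha > 0 else 0.0
        return (np.sqrt(chi2_saxs / self.n_q), np.sqrt(chi2_relax),
                chi2_saxs + self.alpha * chi2_relax)


@dataclass
class SparseSolution:
    """A non-negative sparse weight vector with its fit metrics.

    ``chi_saxs`` is reported in the normalized convention
    sqrt(chi2_saxs / n_q); the unnormalized ``chi2_saxs`` property satisfies
    the identity chi2_total = chi2_saxs + alpha * chi_relax^2.
    """

    support: np.ndarray
    w: np.ndarray
    chi_saxs: float
    chi_relax: float
    chi2_total: float
    alpha: float
    n_q: int = 0

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=int)
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < -1e-12):
            raise SESError("weights must be non-negative")
        off = np.ones(len(self.w), dtype=bool)
        off[self.support] = False
        if np.any(self.w[off] != 0.0):
            raise SESError("weights must vanish off-support")
        if self.n_q:
            ident = self.chi2_saxs + self.alpha * self.chi_relax ** 2
            if not np.isclose(ident, self.chi2_total, rtol=1e-9, atol=1e-9):
                raise SESError("chi^2 identity violated")

    @property
    def chi2_saxs(self):
        return self.chi_saxs ** 2 * self.n_q

    @property
    def size(self):
        return int((self.w[self.support] > 0).sum())

    def populations(self):
        total = self.w.sum()
        if total <= 0:
            raise SESError("zero total weight")
        return self.w / total


@dataclass
class EnsembleModel:
    """Averaged near-optimal solution expressed as populations."""

    populations: np.ndarray
    member_ids: list | None
    alpha: float
    chi_saxs: float
    chi_relax: float
    chi2_total: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=float)
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise SESError("populations must sum to 1")

    def support(self, tol=1e-12):
        return np.flatnonzero(self.populations > tol)

    def to_json(self):
        sup = self.support()
        ids = ([self.member_ids[i] for i in sup] if self.member_ids
               else [int(i) for i in sup])
        return {
            "alpha": self.alpha,
            "chi_saxs": self.chi_saxs,
            "chi_relax": self.chi_relax,
            "chi2_total": self.chi2_total,
            "members": [{"id": mid, "index": int(i),
                         "population": float(self.populations[i])}
                        for mid, i in zip(ids, sup)],
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# chi metrics (stand-alone forms used by tests and reports)


def chi_saxs(w, profiles, exp_profile):
    """Normalized SAXS goodness of fit.

    chi = sqrt( (1/N_q) sum_i [ (sum_k I_k(q_i) w_k - I_exp(q_i)) / sigma_i ]^2 )
    """
    profiles = np.asarray(profiles, dtype=float)
    w = np.asarray(w, dtype=float)
    if profiles.shape[1] != len(w):
        raise SESError("weight / profile-matrix dimension mismatch")
    if exp_profile.sigma is None or np.any(exp_profile.sigma == 0):
        raise SESError("experimental profile needs nonzero sigmas")
    resid = (profiles @ w - exp_profile.I) / exp_profile.sigma
    return float(np.sqrt((resid ** 2).mean()))


def chi_relax(w, taus, exp: DomainTauExperiment):
    """sqrt of the two-term relaxation misfit (weighted tau averages)."""
    w = np.asarray(w, dtype=float)
    ta = np.asarray([t.tau_A for t in taus], dtype=float)
    tb = np.asarray([t.tau_B for t in taus], dtype=float)
    if len(ta) != len(w):
        raise SESError("weight / tau dimension mismatch")
    if exp.sigma_A == 0 or exp.sigma_B == 0:
        raise SESError("zero sigma in tau experiment")
    chi2 = ((ta @ w - exp.tau_A_exp) / exp.sigma_A) ** 2 + \
           ((tb @ w - exp.tau_B_exp) / exp.sigma_B) ** 2
    return float(np.sqrt(chi2))


# ---------------------------------------------------------------------------
# system construction and solvers


def build_design_system(pool_profiles, pool_taus, exp_profile, exp_taus,
                        alpha, member_ids=None, normalize_weights=True):
    """Assemble the (N_q + 2, N_ens) design system of the joint fit.

    With alpha = 0 the two tau rows are zero rows, so only SAXS constrains
    the weights.
    """
    if alpha < 0:
        raise SESError("alpha must be >= 0")
    profiles = np.asarray(pool_profiles, dtype=float)
    n_q, n_ens = profiles.shape
    if pool_taus is not None:
        if len(pool_taus) != n_ens:
            raise SESError(
                f"profile matrix has {n_ens} members but {len(pool_taus)} "
                "tau predictions")
        ta = np.asarray([t.tau_A for t in pool_taus], dtype=float)
        tb = np.asarray([t.tau_B for t in pool_taus], dtype=float)
    else:
        if alpha > 0:
            raise SESError("alpha > 0 requires tau predictions")
        ta = np.zeros(n_ens)
        tb = np.zeros(n_ens)
        exp_taus = DomainTauExperiment(1.0, 1.0, 1.0, 1.0)
    if member_ids is not None and len(member_ids) != n_ens:
        raise SESError("member_ids length mismatch")
    if exp_profile.sigma is None or np.any(exp_profile.sigma == 0):
        raise SESError("experimental profile needs nonzero sigmas")

    sqrt_a = np.sqrt(alpha)
    C = np.vstack([
        profiles / exp_profile.sigma[:, None],
        sqrt_a * ta[None, :] / exp_taus.sigma_A,
        sqrt_a * tb[None, :] / exp_taus.sigma_B,
    ])
    B = np.concatenate([
        exp_profile.I / exp_profile.sigma,
        [sqrt_a * exp_taus.tau_A_exp / exp_taus.sigma_A,
         sqrt_a * exp_taus.tau_B_exp / exp_taus.sigma_B],
    ])
    row_meta = [f"SAXS(q={q:.4f})" for q in exp_profile.q] + ["TAU_A", "TAU_B"]
    return DesignSystem(C, B, float(alpha), row_meta, n_q,
                        member_ids=list(member_ids) if member_ids else None,
                        normalize_weights=normalize_weights)


def _refit(system, support):
    """NNLS refit on a support, with the optional sum-to-one row."""
    Csub = system.C[:, support]
    B = system.B
    if system.normalize_weights:
        Csub = np.vstack([Csub, NORM_ROW_WEIGHT * np.ones((1, len(support)))])
        B = np.concatenate([B, [NORM_ROW_WEIGHT]])
    w_sub, _ = nnls(Csub, B)
    w = np.zeros(system.n_ens)
    w[list(support)] = w_sub
    resid = system.C @ w - system.B
    return w, float(resid @ resid)


def _solution_from(system, support, w):
    cs, cr, c2 = system.chi_parts(w)
    return SparseSolution(np.asarray(sorted(support), dtype=int), w, cs, cr,
                          c2, system.alpha, n_q=system.n_q)


def _swap_refine(system, support, max_rounds=10):
    """Polish a support by exhaustive single-column swaps (local search)."""
    support = list(support)
    w, cost = _refit(system, support)
    for _ in range(max_rounds):
        improved = False
        for pos in range(len(support)):
            for j in range(system.n_ens):
                if j in support:
                    continue
                trial = sorted(support[:pos] + [j] + support[pos + 1:])
                w_t, cost_t = _refit(system, trial)
                if cost_t < cost * (1.0 - 1e-12):
                    support, w, cost = trial, w_t, cost_t
                    improved = True
        if not improved:
            break
    return support, w, cost


def omp_nonneg(system, max_size=20, beam_width=10, branch=5,
               return_beams=False, refine="auto"):
    """Beam-search non-negative orthogonal matching pursuit.

    For each ensemble size s = 1..max_size keeps up to ``beam_width``
    candidate supports; each candidate branches on the ``branch`` columns
    best correlated with its residual, and every support is refit by NNLS.
    Returns the best solution per size (chi^2 non-increasing in s); with
    ``return_beams`` also returns every beam candidate per size, the raw
    material for near-optimal averaging.  Tie-breaking is by lowest column
    index.

    ``refine`` adds exhaustive single-swap polishing of the best support per
    size; "auto" enables it only when ``n_ens * max_size`` is small enough
    for the extra NNLS calls to be cheap.
    """
    if max_size > system.n_ens:
        raise SESError("max_size exceeds the pool size")
    if beam_width < 1:
        raise SESError("beam_width must be >= 1")
    if not np.any(system.B):
        w = np.zeros(system.n_ens)
        sol = _solution_from(system, np.array([], dtype=int), w)
        return ([sol], [[sol]]) if return_beams else [sol]

    col_norms = np.linalg.norm(system.C, axis=0)
    col_norms[col_norms == 0] = 1.0

    beam = [(tuple(), np.zeros(system.n_ens))]
    best_per_size = []
    beams_per_size = []
    best_cost = np.inf
    from math import comb

    for _s in range(1, max_size + 1):
        candidates = set()
        if comb(system.n_ens, _s) <= EXHAUSTIVE_LIMIT:
            # small subset space: enumerate it outright (exact at this size)
            from itertools import combinations
            candidates.update(combinations(range(system.n_ens), _s))
        for support, w in beam:
            resid = system.B - system.C @ w
            corr = (system.C.T @ resid) / col_norms
            order = np.argsort(-corr, kind="stable")
            added = 0
            for j in order:
                if j in support:
                    continue
                candidates.add(tuple(sorted(support + (int(j),))))
                added += 1
                if added >= branch:
                    break
        scored = []
        for sup in sorted(candidates):
            w, cost = _refit(system, list(sup))
            scored.append((cost, sup, w))
        scored.sort(key=lambda t: (t[0], t[1]))
        beam = [(sup, w) for _, sup, w in scored[:beam_width]]
        if return_beams:
            beams_per_size.append([_solution_from(system, sup, w)
                                   for sup, w in beam])
        cost, sup, w = scored[0]
        do_refine = (refine is True or
                     (refine == "auto" and system.n_ens * max_size <= 2000))
        if do_refine:
            sup_r, w_r, cost_r = _swap_refine(system, sup)
            if cost_r < cost:
                sup, w, cost = tuple(sup_r), w_r, cost_r
        if best_per_size and cost > best_cost:
            # nesting with refit cannot worsen; keep the previous best
            best_per_size.append(best_per_size[-1])
        else:
            best_per_size.append(_solution_from(system, sup, w))
            best_cost = cost
    if return_beams:
        return best_per_size, beams_per_size
    return best_per_size


def l_curve_select(chis, warn=None, min_gain=0.20):
    """Ensemble size at the knee of the chi-vs-size curve.

    ``chis`` maps size -> best chi (dict) or is a sequence for sizes 1..n.
    The knee is the largest size whose relative improvement over the previous
    size still exceeds ``min_gain`` (the curve is steep into it and flat
    after); a raw maximum-curvature rule is scale-sensitive when the first
    drop dwarfs the rest.  A flat curve returns size 1 (with ``warn``).
    """
    if isinstance(chis, dict):
        sizes = sorted(chis)
        vals = np.array([chis[s] for s in sizes], dtype=float)
    else:
        vals = np.asarray(list(chis), dtype=float)
        sizes = list(range(1, len(vals) + 1))
    if len(vals) < 3:
        raise SESError("need at least 3 sizes for l-curve selection")
    gains = 1.0 - vals[1:] / np.maximum(vals[:-1], 1e-300)
    signif = np.flatnonzero(gains >= min_gain)
    if len(signif) == 0:
        if warn is not None:
            warn("flat l-curve; defaulting to size 1")
        return sizes[0]
    return sizes[signif[-1] + 1]


def average_near_optimal(solutions, rel_tol=0.05, member_ids=None,
                         system=None):
    """Average weights of all solutions within (1+rel_tol) of the best chi^2,
    renormalized to populations."""
    if not solutions:
        raise SESError("no solutions to average")
    costs = np.array([s.chi2_total for s in solutions])
    keep = costs <= (1.0 + rel_tol) * costs.min()
    w = np.mean([solutions[i].w for i in np.flatnonzero(keep)], axis=0)
    pops = w / w.sum()
    if system is not None:
        cs, cr, c2 = system.chi_parts(w)
    else:
        best = solutions[int(np.argmin(costs))]
        cs, cr, c2 = best.chi_saxs, best.chi_relax, best.chi2_total
    alpha = solutions[0].alpha
    return EnsembleModel(pops, member_ids, alpha, cs, cr, c2,
                         provenance={"averaged": int(keep.sum()),
                                     "rel_tol": rel_tol})


def fit_ensemble(pool_profiles, pool_taus, exp_profile, exp_taus, alpha,
                 max_size=20, beam_width=10, branch=5, rel_tol=0.05,
                 member_ids=None, normalize_weights=True):
    """Full selection at one alpha: OMP -> l-curve size -> averaged model."""
    system = build_design_system(pool_profiles, pool_taus, exp_profile,
                                 exp_taus, alpha, member_ids=member_ids,
                                 normalize_weights=normalize_weights)
    per_size, beams = omp_nonneg(system, max_size=min(max_size, system.n_ens),
                                 beam_width=beam_width, branch=branch,
                                 return_beams=True)
    size = l_curve_select([s.chi2_total for s in per_size])
    # near-optimal pool: every beam candidate (any size) whose chi^2 is
    # within rel_tol of the selected-size best
    ref_cost = per_size[size - 1].chi2_total
    near = [s for beam in beams for s in beam
            if s.chi2_total <= (1 + rel_tol) * ref_cost]
    if not near:
        near = [per_size[size - 1]]
    model = average_near_optimal(near, rel_tol=rel_tol, member_ids=member_ids,
                                 system=system)
    model.provenance.update({"selected_size": size, "alpha": alpha,
                             "max_size": max_size, "beam_width": beam_width})
    return model, per_size


def alpha_scan(pool_profiles, pool_taus, exp_profile, exp_taus, alpha_grid,
               **kwargs):
    """Run the full selection at each alpha.

    Returns rows {alpha, chi_saxs, chi_relax, model}; chi_relax is
    non-increasing and chi_saxs non-decreasing in alpha up to solver
    tolerance.
    """
    alpha_grid = np.atleast_1d(np.asarray(alpha_grid, dtype=float))
    if len(alpha_grid) == 0 or np.any(alpha_grid < 0):
        raise SESError("alpha grid must be non-empty and >= 0")
    rows = []
    for a in np.sort(alpha_grid):
        model, _ = fit_ensemble(pool_profiles, pool_taus, exp_profile,
                                exp_taus, float(a), **kwargs)
        rows.append({"alpha": float(a), "chi_saxs": model.chi_saxs,
                     "chi_relax": model.chi_relax, "model": model})
    return rows


def select_equal_fit_alpha(scan_rows, plateau_tol=0.10):
    """Smallest nonzero alpha whose chi_relax sits within ``plateau_tol`` of
    the large-alpha plateau (the chi_relax at the largest alpha scanned)."""
    rows = sorted(scan_rows, key=lambda r: r["alpha"])
    plateau = rows[-1]["chi_relax"]
    for r in rows:
        if r["alpha"] == 0.0:
            continue
        if r["chi_relax"] <= (1.0 + plateau_tol) * max(plateau, 1e-12):
            return r["alpha"]
    return rows[-1]["alpha"]
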