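"""Coarse SAXS forward model and primary reciprocal/real-space analysis.

Forward prediction is a Debye sum over residue beads with an optional Gaussian
dummy-bead form factor.  Analysis covers Guinier fitting, a regularized
indirect Fourier transform P(r), a Dmax selection rule, the dimensionless
Kratky transform and volume-of-correlation mass estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

#: Gaussian dummy-residue form-factor width (A), calibrated once so a compact
#: reference conformer's Guinier Rg matches its coordinate Rg within 2%
#: (see tests); kept small because beads already carry the coarse geometry.
DEFAULT_BEAD_WIDTH = 1.5

#: protein mass relation constant: Mw[Da] = (Vc^2 / Rg) / VC_MASS_CONST
VC_MASS_CONST = 0.1231

DEFAULT_Q_GRID = np.linspace(0.3 / 30.0, 0.3, 30)  # 30 points on 0 < q <= 0.3


class ProfileError(ValueError):
    pass


@dataclass
class ScatteringProfile:
    """A 1-D scattering profile I(q) with optional per-point uncertainty."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.q):
                raise ProfileError("sigma length mismatch")
        if len(self.q) != len(self.I):
            raise ProfileError("q/I length mismatch")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ProfileError("q must be non-negative and strictly increasing")

    def __len__(self):
        return len(self.q)

    def write(self, path):
        """3-column whitespace ASCII: q, I, sigma ('#' comments)."""
        with open(path, "w") as fh:
            fh.write(f"# {self.meta.get('label', 'scattering profile')}\n")
            fh.write("# q[1/A]  I  sigma\n")
            sig = self.sigma if self.sigma is not None else np.full(len(self), np.nan)
            for q, i, s in zip(self.q, self.I, sig):
                fh.write(f"{q:.6e} {i:.6e} {s:.6e}\n")

    @classmethod
    def read(cls, path, label=None):
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.split()
                if len(parts) < 2:
                    raise ProfileError(f"{path}:{ln}: expected >= 2 columns")
                try:
                    rows.append([float(x) for x in parts[:3]])
                except ValueError as err:
                    raise ProfileError(f"{path}:{ln}: {err}") from None
        arr = np.asarray(rows)
        if arr.ndim != 2:
            raise ProfileError(f"{path}: no data rows")
        sigma = None
        if arr.shape[1] > 2 and np.isfinite(arr[:, 2]).all():
            sigma = arr[:, 2]
        return cls(arr[:, 0], arr[:, 1], sigma,
                   meta={"label": label or str(path)})


@dataclass
class GuinierResult:
    Rg: float
    I0: float
    fit_range: tuple
    n_points: int
    warnings: list = field(default_factory=list)


@dataclass
class PairDistribution:
    r: np.ndarray
    P: np.ndarray
    Dmax: float
    Rg_real: float
    I0_real: float
    reg_weight: float = 0.0
    warnings: list = field(default_factory=list)

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(f"# Dmax = {self.Dmax:.3f} A, Rg_real = {self.Rg_real:.3f} A\n")
            for r, p in zip(self.r, self.P):
                fh.write(f"{r:.4f} {p:.6e}\n")


@dataclass
class VcResult:
    Vc: float
    QR: float
    Mw_Da: float
    q_cut: float


# ---------------------------------------------------------------------------
# forward model


def bead_form_factor(q, width=DEFAULT_BEAD_WIDTH):
    """Gaussian dummy-residue form factor, f(0) = 1."""
    q = np.asarray(q, dtype=float)
    return np.exp(-0.5 * (q * width) ** 2)


def debye_profile(conformer_or_coords, q_grid=None, width=DEFAULT_BEAD_WIDTH):
    """Debye-sum scattering profile of a bead model.

    I(q) = f(q)^2 * [N + 2 * sum_{i<j} sinc(q d_ij)];  I(0) = (N f(0))^2 = N^2.
    """
    coords = getattr(conformer_or_coords, "coords", conformer_or_coords)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise ProfileError("empty or malformed conformer")
    q = np.asarray(DEFAULT_Q_GRID if q_grid is None else q_grid, dtype=float)
    n = len(coords)
    if n == 1:
        I = bead_form_factor(q, width) ** 2
    else:
        d = pdist(coords)
        pair_sums = np.empty(len(q))
        # chunk over q to bound memory for large bead counts
        chunk = max(1, int(2e7 // max(len(d), 1)))
        for i in range(0, len(q), chunk):
            qd = np.outer(q[i:i + chunk], d)
            pair_sums[i:i + chunk] = np.sinc(qd / np.pi).sum(axis=1)
        I = bead_form_factor(q, width) ** 2 * (n + 2.0 * pair_sums)
    label = getattr(conformer_or_coords, "id", "debye")
    return ScatteringProfile(q, I, None, meta={"label": label, "I0": float(n * n)})


def pool_profile_matrix(pool, q_grid=None, width=DEFAULT_BEAD_WIDTH):
    """(N_q, N_ens) matrix of predicted profiles, column order = pool order."""
    q = np.asarray(DEFAULT_Q_GRID if q_grid is None else q_grid, dtype=float)
    mat = np.empty((len(q), pool.size))
    for k, conf in enumerate(pool):
        mat[:, k] = debye_profile(conf, q, width).I
    return mat


# ---------------------------------------------------------------------------
# Guinier


def guinier_fit(profile, qRg_limit=1.3, min_points=5):
    """Self-consistent low-q Guinier fit: ln I = ln I0 - q^2 Rg^2 / 3.

    Starts from a small low-q window and iterates the window so that
    q_max * Rg <= qRg_limit at convergence.
    """
    usable = profile.I > 0
    if usable.sum() < min_points:
        raise ProfileError("fewer than 5 usable points for Guinier fit")
    q, I = profile.q[usable], profile.I[usable]
    warnings = []

    def fit(n):
        slope, intercept = np.polyfit(q[:n] ** 2, np.log(I[:n]), 1)
        if slope >= 0:
            warnings.append("non-negative Guinier slope (aggregation-like)")
            slope = -1e-12
        return float(np.sqrt(-3.0 * slope)), float(np.exp(intercept))

    n = min(max(min_points, 10), len(q))
    seen = set()
    for _ in range(100):
        Rg, I0 = fit(n)
        new_n = int(np.searchsorted(q, qRg_limit / max(Rg, 1e-9), side="right"))
        new_n = min(max(new_n, min_points), len(q))
        if new_n == n:
            break
        if new_n in seen:  # 2-cycle: take the smaller window
            n = min(n, new_n)
            Rg, I0 = fit(n)
            break
        seen.add(n)
        n = new_n
    else:
        raise ProfileError("Guinier range did not converge")
    return GuinierResult(Rg, I0, (float(q[0]), float(q[n - 1])), n, warnings)


# ---------------------------------------------------------------------------
# indirect Fourier transform


def _ift_design(q, r):
    """Kernel A with I(q) = A @ P(r) for trapezoid weights on the r grid."""
    dr = np.gradient(r)
    w = dr.copy()
    w[0] *= 0.5
    w[-1] *= 0.5
    qr = np.outer(q, r)
    return 4.0 * np.pi * np.sinc(qr / np.pi) * w[None, :]


def ift_pr(profile, Dmax, reg_weight=None, n_r=101, guinier=None):
    """Regularized non-negative indirect Fourier transform.

    Solves I(q) = 4 pi * integral P(r) sinc(qr) dr for P >= 0 on an ``n_r``
    point grid with P(0) = P(Dmax) = 0, a second-difference smoothness penalty
    and sigma-weighted residuals.  ``reg_weight=None`` picks the weight by an
    L-curve scan over candidate weights.
    """
    if Dmax <= 0:
        raise ProfileError("Dmax must be positive")
    if profile.sigma is None:
        raise ProfileError("IFT requires a profile with uncertainties")
    n_r = max(n_r, 101)
    warnings = []
    if guinier is None:
        try:
            guinier = guinier_fit(profile)
        except ProfileError:
            guinier = None
    if guinier is not None and Dmax < 2.0 * guinier.Rg:
        warnings.append(f"Dmax={Dmax:.1f} < 2*Rg={2 * guinier.Rg:.1f}")

    r = np.linspace(0.0, Dmax, n_r)
    A = _ift_design(profile.q, r)
    # endpoint constraints: drop the fixed-zero first/last columns
    A_in = A[:, 1:-1] / profile.sigma[:, None]
    b = profile.I / profile.sigma
    m = n_r - 2
    D2 = (np.diag(np.full(m, -2.0)) + np.diag(np.ones(m - 1), 1)
          + np.diag(np.ones(m - 1), -1))
    scale = np.linalg.norm(A_in) / np.linalg.norm(D2)

    def solve(lam):
        M = np.vstack([A_in, lam * scale * D2])
        rhs = np.concatenate([b, np.zeros(m)])
        x, _ = nnls(M, rhs)
        resid = A_in @ x - b
        rough = D2 @ x
        return x, float(resid @ resid), float(rough @ rough)

    if reg_weight is None:
        lams = np.logspace(-4, 1, 12)
        results = [solve(lam) for lam in lams]
        lx = np.log10([max(res, 1e-300) for _, res, _ in results])
        ly = np.log10([max(rg, 1e-300) for _, _, rg in results])
        curv = np.full(len(lams), -np.inf)
        for i in range(1, len(lams) - 1):
            v1 = np.array([lx[i] - lx[i - 1], ly[i] - ly[i - 1]])
            v2 = np.array([lx[i + 1] - lx[i], ly[i + 1] - ly[i]])
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom > 0:
                curv[i] = cross / denom
        best = int(np.argmax(curv)) if np.isfinite(curv).any() else len(lams) // 2
        reg_weight = float(lams[best])
    x, resid2, _ = solve(reg_weight)

    P = np.zeros(n_r)
    P[1:-1] = x
    total = np.trapezoid(P, r)
    if total <= 0:
        raise ProfileError("singular IFT system: P(r) identically zero")
    Rg_real = float(np.sqrt(np.trapezoid(r ** 2 * P, r) / (2.0 * total)))
    I0_real = float(4.0 * np.pi * total)
    return PairDistribution(r, P, float(Dmax), Rg_real, I0_real,
                            reg_weight=reg_weight, warnings=warnings)


def back_transform(pr, q):
    """I(q) predicted from a pair distribution (self-consistency check)."""
    A = _ift_design(np.asarray(q, dtype=float), pr.r)
    return A @ pr.P


def choose_dmax(profile, candidates, reg_weight=None, tail_frac=0.10,
                tail_level=0.10):
    """Smallest candidate Dmax whose P(r) tail is flat near zero.

    Criterion: mean |P| over the last ``tail_frac`` of the r range at most
    ``tail_level`` of the peak.  Returns ``(Dmax, fallback)`` where
    ``fallback`` is True when no candidate qualified and the largest was
    returned with a warning.
    """
    candidates = sorted(float(c) for c in np.atleast_1d(candidates))
    if len(candidates) == 0:
        raise ProfileError("need at least one candidate Dmax")
    if len(candidates) == 1:
        return candidates[0], False
    for c in candidates:
        pr = ift_pr(profile, c, reg_weight=reg_weight)
        ntail = max(2, int(np.ceil(tail_frac * len(pr.r))))
        tail = np.abs(pr.P[-ntail:]).mean()
        if tail <= tail_level * pr.P.max():
            return c, False
    return candidates[-1], True


# ---------------------------------------------------------------------------
# Kratky, Vc, mass


def kratky_dimensionless(profile, Rg, I0):
    """Dimensionless Kratky curve: x = q Rg, y = (q Rg)^2 I / I0.

    Returns (x, y, peak_x, peak_y).  A compact globule peaks near
    (sqrt(3), 3/e); flexibility shifts the peak right and up.
    """
    if Rg <= 0 or I0 <= 0:
        raise ProfileError("Rg and I0 must be positive")
    x = profile.q * Rg
    y = x ** 2 * profile.I / I0
    ipk = int(np.argmax(y))
    return x, y, float(x[ipk]), float(y[ipk])


def volume_of_correlation(profile, I0, Rg, q_cut=0.3):
    """Volume of correlation and the protein mass estimate it implies.

    Vc = I0 / integral_0^q_cut q I(q) dq with an analytic Guinier extension
    below the first measured point; QR = Vc^2 / Rg; Mw = QR / 0.1231 Da.
    """
    if q_cut > profile.q[-1] + 1e-12:
        raise ProfileError(f"q_cut={q_cut} beyond data range {profile.q[-1]}")
    sel = profile.q <= q_cut + 1e-12
    q, I = profile.q[sel], profile.I[sel]
    integral = float(np.trapezoid(q * I, q))
    q1 = q[0]
    # analytic integral of q*I0*exp(-q^2 Rg^2/3) over [0, q1]
    integral += float(I0 * 1.5 / Rg ** 2 * (1.0 - np.exp(-q1 ** 2 * Rg ** 2 / 3.0)))
    Vc = I0 / integral
    QR = Vc ** 2 / Rg
    return VcResult(float(Vc), float(QR), float(QR / VC_MASS_CONST), float(q_cut))


def mass_from_vc(Vc, Rg):
    """Protein mass (Da) from the volume of correlation: (Vc^2/Rg)/0.1231."""
    if Vc <= 0 or Rg <= 0:
        raise ProfileError("Vc and Rg must be positive")
    return (Vc ** 2 / Rg) / VC_MASS_CONST
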