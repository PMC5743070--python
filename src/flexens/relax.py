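"""Amide 15N relaxation: forward model, local tau_c, diffusion-tensor fits.

Standard dipolar + CSA rate expressions with model-free spectral densities.
Isotropic and axially symmetric rotational diffusion are supported; the axial
model uses the three-exponential spectral density whose amplitudes depend on
the angle between each NH bond and the symmetry axis.

Conventions (MODELFREE-era): r_NH = 1.02 A, Delta-sigma(15N CSA) = -172 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

# physical constants (SI)
MU0 = 4.0e-7 * np.pi
HBAR = 1.054571817e-34
GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
GAMMA_N = -2.7116e7
R_NH = 1.02e-10  # m
CSA_N = -172.0e-6

NOE_SANITY_MAX = 1.2
RIGID_NOE_MIN = 0.65  # residues below this are excluded from tensor fits


class RelaxError(ValueError):
    pass


@dataclass
class RelaxationDataset:
    """Per-residue T1/T2/NOE records at one field, with NH orientations.

    ``table`` columns: residue, domain, T1, sT1, T2, sT2, NOE, sNOE (seconds
    for times).  ``nh_vectors`` is an optional (N, 3) array of unit vectors in
    the molecular frame, row-aligned with ``table``.
    """

    table: pd.DataFrame
    field_MHz: float
    nh_vectors: np.ndarray | None = None

    def __post_init__(self):
        req = {"residue", "domain", "T1", "sT1", "T2", "sT2", "NOE", "sNOE"}
        missing = req - set(self.table.columns)
        if missing:
            raise RelaxError(f"missing columns: {sorted(missing)}")
        if self.field_MHz <= 0:
            raise RelaxError("field_MHz must be positive")
        t = self.table
        if not ((t.T1 > t.T2) & (t.T2 > 0)).all():
            raise RelaxError("need T1 > T2 > 0 for every residue")
        if (t.NOE > NOE_SANITY_MAX).any():
            raise RelaxError(f"NOE above sanity bound {NOE_SANITY_MAX}")
        if self.nh_vectors is not None:
            self.nh_vectors = np.asarray(self.nh_vectors, dtype=float)
            if self.nh_vectors.shape != (len(t), 3):
                raise RelaxError("nh_vectors shape mismatch")

    def __len__(self):
        return len(self.table)

    def subset(self, domain):
        mask = (self.table.domain == domain).to_numpy()
        if not mask.any():
            raise RelaxError(f"no residues in domain {domain!r}")
        nh = self.nh_vectors[mask] if self.nh_vectors is not None else None
        return RelaxationDataset(self.table[mask].reset_index(drop=True),
                                 self.field_MHz, nh)

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(f"# field_MHz = {self.field_MHz}\n")
            cols = ["residue", "domain", "T1", "sT1", "T2", "sT2", "NOE", "sNOE"]
            if self.nh_vectors is not None:
                fh.write("# columns: " + " ".join(cols + ["nhx", "nhy", "nhz"]) + "\n")
                for i, row in self.table.iterrows():
                    v = self.nh_vectors[i]
                    fh.write(" ".join(str(row[c]) for c in cols) +
                             f" {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            else:
                fh.write("# columns: " + " ".join(cols) + "\n")
                for _, row in self.table.iterrows():
                    fh.write(" ".join(str(row[c]) for c in cols) + "\n")

    @classmethod
    def read(cls, path):
        field = None
        rows = []
        vecs = []
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if s.startswith("#"):
                    if "field_MHz" in s:
                        field = float(s.split("=")[1])
                    continue
                if not s:
                    continue
                p = s.split()
                rows.append([int(p[0]), p[1]] + [float(x) for x in p[2:8]])
                if len(p) >= 11:
                    vecs.append([float(x) for x in p[8:11]])
        if field is None:
            raise RelaxError(f"{path}: missing '# field_MHz =' header")
        tab = pd.DataFrame(rows, columns=["residue", "domain", "T1", "sT1",
                                          "T2", "sT2", "NOE", "sNOE"])
        nh = np.asarray(vecs) if len(vecs) == len(rows) and vecs else None
        return cls(tab, field, nh)


@dataclass
class DiffusionFit:
    """Fitted rotational diffusion tensor."""

    model: str  # "ISOTROPIC" | "AXIAL"
    tau_m: float  # ns
    D_par: float  # s^-1
    D_per: float  # s^-1
    axis: np.ndarray | None = None
    reduced_chi2: float = np.nan
    tau_m_err: float = np.nan

    def __post_init__(self):
        tm = 1.0 / (2.0 * (self.D_par + 2.0 * self.D_per)) * 1e9
        if abs(tm - self.tau_m) > 1e-6 * self.tau_m:
            raise RelaxError("tau_m inconsistent with 1/(2(D_par + 2 D_per))")
        if self.D_par < self.D_per:  # anisotropy >= 1 by convention
            raise RelaxError("convention requires D_par >= D_per")

    @property
    def anisotropy(self):
        return self.D_par / self.D_per


@dataclass
class DomainTauExperiment:
    """Per-domain experimental correlation times feeding the joint fit."""

    tau_A_exp: float
    sigma_A: float
    tau_B_exp: float
    sigma_B: float

    def __post_init__(self):
        if min(self.tau_A_exp, self.tau_B_exp) <= 0:
            raise RelaxError("correlation times must be positive")
        if min(self.sigma_A, self.sigma_B) <= 0:
            raise RelaxError("sigmas must be positive")

    def to_json(self):
        return {"tau_A_exp": self.tau_A_exp, "sigma_A": self.sigma_A,
                "tau_B_exp": self.tau_B_exp, "sigma_B": self.sigma_B}

    @classmethod
    def from_json(cls, d):
        return cls(d["tau_A_exp"], d["sigma_A"], d["tau_B_exp"], d["sigma_B"])


# ---------------------------------------------------------------------------
# spectral densities and rates


def _frequencies(field_MHz):
    wH = 2.0 * np.pi * field_MHz * 1e6
    wN = wH * GAMMA_N / GAMMA_H
    return wH, wN


def _dipolar_csa(field_MHz):
    _, wN = _frequencies(field_MHz)
    d = MU0 * HBAR * GAMMA_H * GAMMA_N / (4.0 * np.pi * R_NH ** 3)
    c2 = (wN * CSA_N) ** 2 / 3.0
    return d * d / 4.0, c2


def _axial_amplitudes(cos_theta):
    c2 = cos_theta * cos_theta
    s2 = 1.0 - c2
    return np.array([(3.0 * c2 - 1.0) ** 2 / 4.0,
                     3.0 * s2 * c2,
                     0.75 * s2 * s2])


def _axial_taus(D_par, D_per):
    return np.array([1.0 / (6.0 * D_per),
                     1.0 / (5.0 * D_per + D_par),
                     1.0 / (2.0 * D_per + 4.0 * D_par)])


def spectral_density(omega, taus, amps, S2=1.0, tau_e=0.0):
    """Model-free J(omega) for a multi-exponential global correlation.

    J = (2/5) sum_j A_j [S2 tau_j/(1+(w tau_j)^2)
                         + (1-S2) tau'_j/(1+(w tau'_j)^2)],
    1/tau'_j = 1/tau_j + 1/tau_e.
    """
    scalar = np.ndim(omega) == 0
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    taus = np.atleast_1d(taus)
    amps = np.atleast_1d(amps)
    J = np.zeros_like(omega)
    for A, t in zip(amps, taus):
        J += A * S2 * t / (1.0 + (omega * t) ** 2)
        if S2 < 1.0 and tau_e > 0.0:
            tp = 1.0 / (1.0 / t + 1.0 / tau_e)
            J += A * (1.0 - S2) * tp / (1.0 + (omega * tp) ** 2)
        elif S2 < 1.0 and tau_e == 0.0:
            pass  # tau_e -> 0 contributes nothing
    J = 0.4 * J
    return float(J[0]) if scalar else J


def predict_relaxation(tau_m=None, S2=1.0, tau_e=0.0, nh_vector=None,
                       field_MHz=800.0, diffusion=None):
    """(R1, R2, NOE) for one NH site.

    Either ``tau_m`` (ns, isotropic) or ``diffusion`` (a DiffusionFit; AXIAL
    requires ``nh_vector``) must be given.  ``tau_e`` in ps.
    """
    if not (0.0 <= S2 <= 1.0):
        raise RelaxError("S2 must lie in [0, 1]")
    if tau_e < 0:
        raise RelaxError("tau_e must be >= 0")
    if diffusion is not None and diffusion.model == "AXIAL":
        if nh_vector is None:
            raise RelaxError("AXIAL model requires an NH vector")
        axis = diffusion.axis / np.linalg.norm(diffusion.axis)
        v = np.asarray(nh_vector, dtype=float)
        cos_t = float(np.clip(v @ axis / np.linalg.norm(v), -1.0, 1.0))
        amps = _axial_amplitudes(cos_t)
        taus = _axial_taus(diffusion.D_par, diffusion.D_per)
    else:
        tm = diffusion.tau_m if diffusion is not None else tau_m
        if tm is None:
            raise RelaxError("need tau_m or a diffusion tensor")
        amps = np.array([1.0])
        taus = np.array([tm * 1e-9])

    wH, wN = _frequencies(field_MHz)
    d2, c2 = _dipolar_csa(field_MHz)
    te = tau_e * 1e-12

    def J(w):
        return float(spectral_density(w, taus, amps, S2, te))

    J0, JN, JH = J(0.0), J(abs(wN)), J(wH)
    JmHN, JpHN = J(abs(wH - abs(wN))), J(wH + abs(wN))
    R1 = d2 * (JmHN + 3.0 * JN + 6.0 * JpHN) + c2 * JN
    R2 = 0.5 * d2 * (4.0 * J0 + JmHN + 3.0 * JN + 6.0 * JH + 6.0 * JpHN) \
        + c2 / 6.0 * (4.0 * J0 + 3.0 * JN)
    noe = 1.0 + d2 * (GAMMA_H / GAMMA_N) * (6.0 * JpHN - JmHN) / R1
    return float(R1), float(R2), float(noe)


# ---------------------------------------------------------------------------
# inversions


def _rigid_ratio(tau_ns, field_MHz):
    r1, r2, _ = predict_relaxation(tau_m=tau_ns, S2=1.0, tau_e=0.0,
                                   field_MHz=field_MHz)
    return r2 / r1


def local_tau_from_ratio(T1, T2, field_MHz, bracket=(0.1, 100.0)):
    """Per-residue correlation time (ns) from the rigid-rotor T1/T2 ratio."""
    if T1 / T2 <= 1.0:
        raise RelaxError("need T1/T2 > 1")
    target = T1 / T2  # = R2/R1
    lo, hi = bracket
    f_lo = _rigid_ratio(lo, field_MHz) - target
    f_hi = _rigid_ratio(hi, field_MHz) - target
    if f_lo > 0:
        raise RelaxError(
            "T1/T2 ratio below the rigid-rotor minimum (fast-limit data)")
    if f_hi < 0:
        raise RelaxError(f"T1/T2 ratio beyond tau_c = {hi} ns")
    return float(brentq(lambda t: _rigid_ratio(t, field_MHz) - target, lo, hi,
                        xtol=1e-6))


def _tensor_from_params(tau_m_ns, anisotropy):
    D_iso = 1.0 / (6.0 * tau_m_ns * 1e-9)
    D_par = 3.0 * D_iso * anisotropy / (anisotropy + 2.0)
    D_per = 3.0 * D_iso / (anisotropy + 2.0)
    return D_par, D_per

def _axis_from_angles(theta, phi):
    return np.array([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(theta)])


def _predict_dataset(data, tau_m_ns, anisotropy, theta, phi):
    D_par, D_per = _tensor_from_params(tau_m_ns, anisotropy)
    axis = _axis_from_angles(theta, phi)
    taus = _axial_taus(D_par, D_per)
    out = np.empty((len(data), 3))
    for i in range(len(data)):
        if anisotropy == 1.0 or data.nh_vectors is None:
            amps = np.array([1.0])
            t = np.array([tau_m_ns * 1e-9])
        else:
            v = data.nh_vectors[i]
            cos_t = float(np.clip(v @ axis / np.linalg.norm(v), -1.0, 1.0))
            amps = _axial_amplitudes(cos_t)
            t = taus
        wH, wN = _frequencies(data.field_MHz)
        d2, c2 = _dipolar_csa(data.field_MHz)

        def J(w):
            return float(spectral_density(w, t, amps))

        J0, JN, JH = J(0.0), J(abs(wN)), J(wH)
        JmHN, JpHN = J(abs(wH - abs(wN))), J(wH + abs(wN))
        R1 = d2 * (JmHN + 3.0 * JN + 6.0 * JpHN) + c2 * JN
        R2 = 0.5 * d2 * (4.0 * J0 + JmHN + 3.0 * JN + 6.0 * JH + 6.0 * JpHN) \
            + c2 / 6.0 * (4.0 * J0 + 3.0 * JN)
        noe = 1.0 + d2 * (GAMMA_H / GAMMA_N) * (6.0 * JpHN - JmHN) / R1
        out[i] = (R1, R2, noe)
    return out


def _observed(data):
    t = data.table
    obs = np.column_stack([1.0 / t.T1, 1.0 / t.T2, t.NOE])
    # error propagation: s(1/T) = sT / T^2
    sig = np.column_stack([t.sT1 / t.T1 ** 2, t.sT2 / t.T2 ** 2, t.sNOE])
    return obs, sig


def fit_diffusion_tensor(data, model="AXIAL", noe_min=RIGID_NOE_MIN,
                         n_starts=8):
    """Least-squares rotational diffusion tensor from R1/R2/NOE.

    Residues with NOE < ``noe_min`` are excluded (flexible sites).  S2 is
    fixed at 1 for tensor estimation.  AXIAL fits (tau_m, anisotropy, axis)
    with multiple deterministic axis starts; ISOTROPIC fits tau_m alone.
    """
    model = model.upper()
    if model not in ("ISOTROPIC", "AXIAL"):
        raise RelaxError(f"unknown model {model!r}")
    keep = (data.table.NOE >= noe_min).to_numpy()
    nh = data.nh_vectors[keep] if data.nh_vectors is not None else None
    sub = RelaxationDataset(data.table[keep].reset_index(drop=True),
                            data.field_MHz, nh)
    if model == "AXIAL" and (sub.nh_vectors is None or len(sub) < 5):
        raise RelaxError("AXIAL fit needs >= 5 rigid residues with NH vectors")
    obs, sig = _observed(sub)

    # tau_m start from the median rigid-rotor inversion
    taus0 = []
    for _, row in sub.table.iterrows():
        try:
            taus0.append(local_tau_from_ratio(row.T1, row.T2, sub.field_MHz))
        except RelaxError:
            continue
    tau0 = float(np.median(taus0)) if taus0 else 10.0

    def residuals(p):
        if model == "ISOTROPIC":
            tm, ani, th, ph = p[0], 1.0, 0.0, 0.0
        else:
            tm, ani, th, ph = p
        calc = _predict_dataset(sub, tm, max(ani, 1.0 + 1e-12), th, ph)
        return ((calc - obs) / sig).ravel()

    if model == "ISOTROPIC":
        sol = least_squares(residuals, x0=[tau0], bounds=([0.1], [200.0]))
        best = sol
        tm, ani = float(sol.x[0]), 1.0
        axis = None
    else:
        starts = []
        golden = np.pi * (3.0 - np.sqrt(5.0))
        for i in range(n_starts):  # deterministic Fibonacci-sphere starts
            z = 1.0 - (i + 0.5) / n_starts
            starts.append((np.arccos(z), (i * golden) % (2.0 * np.pi)))
        best = None
        for th0, ph0 in starts:
            sol = least_squares(
                residuals, x0=[tau0, 1.2, th0, ph0],
                bounds=([0.1, 1.0, -np.pi, -2.0 * np.pi],
                        [200.0, 10.0, 2.0 * np.pi, 4.0 * np.pi]))
            if best is None or sol.cost < best.cost:
                best = sol
        tm, ani = float(best.x[0]), float(best.x[1])
        axis = _axis_from_angles(best.x[2], best.x[3])
        if axis[2] < 0:
            axis = -axis
    if not best.success and best.status <= 0:
        raise RelaxError(f"tensor fit did not converge: {best.message}")

    dof = max(obs.size - len(best.x), 1)
    red_chi2 = float(2.0 * best.cost / dof)
    D_par, D_per = _tensor_from_params(tm, ani)
    # 1-sigma tau_m error from the Jacobian (Gauss-Newton covariance)
    try:
        J = best.jac
        cov = np.linalg.pinv(J.T @ J) * max(red_chi2, 1.0)
        tm_err = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        tm_err = np.nan
    return DiffusionFit(model, tm, D_par, D_per, axis=axis,
                        reduced_chi2=red_chi2, tau_m_err=tm_err)


def domain_taus(fit_a, fit_b, min_sigma=1e-3):
    """Package two per-domain tensor fits as the joint-fit targets."""
    if fit_a is None or fit_b is None:
        raise RelaxError("both domains must be fitted")
    sa = fit_a.tau_m_err if np.isfinite(fit_a.tau_m_err) else min_sigma
    sb = fit_b.tau_m_err if np.isfinite(fit_b.tau_m_err) else min_sigma
    return DomainTauExperiment(fit_a.tau_m, max(sa, min_sigma),
                               fit_b.tau_m, max(sb, min_sigma))
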