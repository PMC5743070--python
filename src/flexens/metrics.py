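"""Descriptors of weighted conformer ensembles.

Population-weighted Rg and reference-distance (d_RM) distributions, the
bound-state percentage, and domain center-of-mass maps in a common frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pool import BOUND, DOMAIN_A, DOMAIN_B, ValidationError

DEFAULT_DRM_BOUND_THRESHOLD = 12.0  # A, label-free bound/open classifier


@dataclass
class WeightedDistribution:
    """A weight-normalized histogram with detected peaks."""

    bin_edges: np.ndarray
    density: np.ndarray
    peaks: list = field(default_factory=list)  # (location, height)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValidationError("density must be non-negative")
        widths = np.diff(self.bin_edges)
        total = float((self.density * widths).sum())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"density integrates to {total}, not 1")

    @property
    def bin_centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def major_peak(self):
        if not self.peaks:
            raise ValidationError("no peaks detected")
        return max(self.peaks, key=lambda p: p[1])

    def write(self, path):
        with open(path, "w") as fh:
            fh.write("# bin_center density\n")
            for c, d in zip(self.bin_centers, self.density):
                fh.write(f"{c:.4f} {d:.6e}\n")


def _detect_peaks(centers, density, rel_height=0.10):
    """Local maxima above ``rel_height`` of the global maximum."""
    if density.max() <= 0:
        return []
    peaks = []
    thr = rel_height * density.max()
    for i in range(len(density)):
        left = density[i - 1] if i > 0 else -np.inf
        right = density[i + 1] if i < len(density) - 1 else -np.inf
        if density[i] >= thr and density[i] > left and density[i] >= right:
            peaks.append((float(centers[i]), float(density[i])))
    return peaks


def _weighted_hist(values, weights, bins):
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(values) != len(weights):
        raise ValidationError("values/weights length mismatch")
    if weights.sum() <= 0:
        raise ValidationError("weights sum to zero")
    density, edges = np.histogram(values, bins=bins, weights=weights,
                                  density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return WeightedDistribution(edges, density,
                                _detect_peaks(centers, density))


def rg_distribution(pool, populations, bins=30):
    """Population-weighted histogram of per-conformer coordinate Rg."""
    if pool.size == 0:
        raise ValidationError("empty pool")
    rgs = np.array([m.rg() for m in pool])
    return _weighted_hist(rgs, populations, bins)


def drm_distribution(pool, populations, bins=30):
    """Population-weighted histogram of the linker/groove reference distance."""
    drms = np.array([m.d_rm() for m in pool])
    return _weighted_hist(drms, populations, bins)


def p_bound(pool, populations, classifier="LABEL",
            drm_threshold=DEFAULT_DRM_BOUND_THRESHOLD):
    """Population-weighted bound-state percentage.

    ``classifier`` is "LABEL" (generation-time linker state) or
    "DRM_THRESHOLD" (d_RM <= threshold counts as bound).
    """
    populations = np.asarray(populations, dtype=float)
    if len(populations) != pool.size:
        raise ValidationError("populations/pool length mismatch")
    total = populations.sum()
    if total <= 0:
        raise ValidationError("populations sum to zero")
    if classifier.upper() == "LABEL":
        mask = np.array([m.linker_state == BOUND for m in pool])
    elif classifier.upper() == "DRM_THRESHOLD":
        mask = np.array([m.d_rm() <= drm_threshold for m in pool])
    else:
        raise ValidationError(f"unknown classifier {classifier!r}")
    return float(populations[mask].sum() / total * 100.0)


def kabsch_rotation(mobile, target):
    """Least-squares rotation matrix mapping centred ``mobile`` onto
    centred ``target``."""
    H = mobile.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_on_segment(conformer, reference, segment=DOMAIN_A):
    """Conformer coordinates after rigid superposition of one segment onto
    the reference's matching segment (Kabsch)."""
    idx = np.flatnonzero(conformer.segments == segment)
    idx_ref = np.flatnonzero(reference.segments == segment)
    if len(idx) != len(idx_ref) or len(idx) < 3:
        raise ValidationError("segments not alignable")
    mob = conformer.coords[idx]
    tgt = reference.coords[idx_ref]
    mc, tc = mob.mean(axis=0), tgt.mean(axis=0)
    R = kabsch_rotation(mob - mc, tgt - tc)
    return (conformer.coords - mc) @ R.T + tc


def domain_com_map(pool, populations, reference=None):
    """Domain-B centers of mass in the shared domain-A frame.

    Returns a list of ((x, y, z), weight) after superposing every member's
    domain A onto the reference (first member by default).
    """
    populations = np.asarray(populations, dtype=float)
    ref = reference if reference is not None else pool.members[0]
    out = []
    for m, w in zip(pool, populations):
        coords = superpose_on_segment(m, ref, DOMAIN_A)
        com_b = coords[m.segments == DOMAIN_B].mean(axis=0)
        out.append((com_b, float(w)))
    return out


def write_com_map(com_map, path):
    with open(path, "w") as fh:
        fh.write("# x y z weight\n")
        for pos, w in com_map:
            fh.write(f"{pos[0]:.3f} {pos[1]:.3f} {pos[2]:.3f} {w:.6e}\n")
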