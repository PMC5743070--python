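"""Coarse bead-chain conformers of a two-domain protein with a flexible linker.

One bead per residue at virtual C-alpha positions, 3.8 A bonds, hard-sphere
excluded volume.  Conformers come in two linker modes: BOUND (linker tracks a
groove path on domain A, only the short hinge is flexible) and OPEN (the whole
linker is a self-avoiding random chain).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

BOND_LENGTH = 3.8  # A, virtual CA-CA bond
BOND_TOL = 0.01
MIN_DIST = 4.0  # A, hard-sphere excluded volume between non-bonded beads
HINGE_LEN = 5  # flexible hinge at the domain-B end of the linker
GROOVE_STANDOFF = 3.0  # A, groove path height above the domain-A surface
GROOVE_CONTACT = 8.0  # A, max d_RM for a bound linker
VOLUME_PER_RESIDUE = 134.0  # A^3, average amino-acid volume

DOMAIN_A = "DOMAIN_A"
DOMAIN_B = "DOMAIN_B"
LINKER = "LINKER"
HINGE = "HINGE"
TAG_TAIL = "TAG_TAIL"
FLEX_LOOP = "FLEX_LOOP"

BOUND = "BOUND"
OPEN = "OPEN"

_CHAIN_ID = {DOMAIN_A: "A", DOMAIN_B: "B", LINKER: "L", HINGE: "H",
             TAG_TAIL: "T", FLEX_LOOP: "F"}
_SEG_FROM_CHAIN = {v: k for k, v in _CHAIN_ID.items()}


class GenerationError(RuntimeError):
    """Chain growth failed after the retry budget (steric trap)."""

    def __init__(self, msg: str, retries: int = 0):
        super().__init__(msg)
        self.retries = retries


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Conformer:
    """A single bead-chain conformer.

    Attributes
    ----------
    coords : (N, 3) float array, bead positions in Angstrom.
    segments : (N,) array of segment tags.
    linker_state : "BOUND" or "OPEN".
    ref_linker_bead : index of the linker reference bead (d_RM endpoint).
    ref_groove_bead : index of the domain-A groove reference bead.
    id : opaque identifier.
    """

    coords: np.ndarray
    segments: np.ndarray
    linker_state: str
    ref_linker_bead: int
    ref_groove_bead: int
    id: str
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        segments = np.asarray(self.segments)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "segments", segments)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError("coords must be (N, 3)")
        if len(segments) != len(coords):
            raise ValidationError("segments length mismatch")
        if self.linker_state not in (BOUND, OPEN):
            raise ValidationError(f"bad linker_state {self.linker_state!r}")
        n = len(coords)
        if not (0 <= self.ref_linker_bead < n and 0 <= self.ref_groove_bead < n):
            raise ValidationError("reference bead index out of range")
        if (segments == LINKER).any():  # single-domain test fixtures have none
            if segments[self.ref_linker_bead] != LINKER:
                raise ValidationError(
                    "ref_linker_bead must lie in the LINKER segment")
            if segments[self.ref_groove_bead] != DOMAIN_A:
                raise ValidationError("ref_groove_bead must lie in DOMAIN_A")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def segment_indices(self, tag: str) -> np.ndarray:
        return np.flatnonzero(self.segments == tag)

    def rg(self) -> float:
        """Radius of gyration of the bead coordinates."""
        d = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((d * d).sum(axis=1).mean()))

    def d_rm(self) -> float:
        """Distance between the linker and groove reference beads."""
        return float(np.linalg.norm(
            self.coords[self.ref_linker_bead] - self.coords[self.ref_groove_bead]))

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def min_nonbonded_distance(self) -> float:
        d = pdist(self.coords)
        n = self.n_beads
        # mask out bonded (consecutive) pairs in condensed-form indexing
        idx = np.cumsum(np.arange(n - 1, 0, -1)) - np.arange(n - 1, 0, -1)
        mask = np.ones(len(d), dtype=bool)
        mask[idx] = False
        return float(d[mask].min()) if mask.any() else np.inf

    def validate_geometry(self, min_dist: float = MIN_DIST) -> None:
        b = self.bond_lengths()
        if np.any(np.abs(b - BOND_LENGTH) > BOND_TOL):
            raise ValidationError(
                f"bond length out of tolerance: {b.min():.3f}..{b.max():.3f}")
        if self.min_nonbonded_distance() < min_dist - 1e-9:
            raise ValidationError("excluded-volume violation")


@dataclass
class ConformerPool:
    """A pool of conformers sharing one bead layout."""

    members: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValidationError("pool must contain at least one member")
        n0 = self.members[0].n_beads
        seg0 = self.members[0].segments
        for m in self.members[1:]:
            if m.n_beads != n0 or not np.array_equal(m.segments, seg0):
                raise ValidationError("pool members must share one bead layout")

    @property
    def size(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i):
        return self.members[i]

    def ids(self) -> list:
        return [m.id for m in self.members]

    def bound_fraction(self) -> float:
        return sum(m.linker_state == BOUND for m in self.members) / self.size


# ---------------------------------------------------------------------------
# chain growth primitives


def _random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _clashes(candidate, existing, skip_last=True, min_dist=MIN_DIST):
    """candidate (3,) against existing (M,3); the bonded predecessor is skipped."""
    pts = existing[:-1] if skip_last else existing
    if len(pts) == 0:
        return False
    d2 = ((pts - candidate) ** 2).sum(axis=1)
    return bool((d2 < min_dist ** 2).any())


def _grow_free_chain(start, n_steps, rng, obstacles, bias_dir=None, bias=0.0,
                     max_retries=1000):
    """Grow a self-avoiding chain of ``n_steps`` beads from ``start``.

    ``obstacles`` are fixed beads the chain must avoid (the bead bonded to the
    first new bead must be obstacles[-1]).  ``bias`` > 0 adds directional
    persistence toward ``bias_dir`` (or the previous step direction).
    """
    chain = []
    retries = 0
    prev_dir = bias_dir
    pos = np.asarray(start, dtype=float)
    while len(chain) < n_steps:
        placed = False
        for _ in range(60):
            d = _random_unit(rng)[0]
            if bias > 0.0 and prev_dir is not None:
                d = d + bias * prev_dir
                d = d / np.linalg.norm(d)
            cand = pos + BOND_LENGTH * d
            fixed_ok = not _clashes(cand, obstacles, skip_last=len(chain) == 0)
            own_ok = (len(chain) <= 1 or
                      not _clashes(cand, np.asarray(chain), skip_last=True))
            if fixed_ok and own_ok:
                chain.append(cand)
                pos = cand
                prev_dir = d if bias > 0.0 else prev_dir
                placed = True
                break
        if not placed:
            retries += 1
            if retries > max_retries:
                raise GenerationError(
                    f"chain growth stuck after {retries} retries", retries)
            # backtrack a few beads and try again
            k = min(len(chain), 3)
            del chain[len(chain) - k:]
            pos = chain[-1] if chain else np.asarray(start, dtype=float)
            prev_dir = bias_dir
    return np.asarray(chain)


def _grow_compact_cluster(n_beads, semi_axes, rng, max_restarts=200):
    """Self-avoiding chain filling an ellipsoid of the given semi-axes.

    The chain STARTS at the surface along the +x semi-axis; callers reverse
    bead order when the chain must end there.
    """
    a = np.asarray(semi_axes, dtype=float)
    start = np.array([a[0] - 2.2, 0.0, 0.0])

    def inside(p):
        return ((p / a) ** 2).sum() <= 1.0

    for _ in range(max_restarts):
        chain = [start.copy()]
        pos = start.copy()
        stuck = 0
        ok = True
        while len(chain) < n_beads:
            placed = False
            # bias candidates toward the interior when near the surface
            for _ in range(80):
                d = _random_unit(rng)[0]
                cand = pos + BOND_LENGTH * d
                if not inside(cand):
                    continue
                if len(chain) >= 2 and _clashes(cand, np.asarray(chain)):
                    continue
                chain.append(cand)
                pos = cand
                placed = True
                break
            if not placed:
                stuck += 1
                if stuck > 400:
                    ok = False
                    break
                k = min(len(chain) - 1, 4)
                if k <= 0:
                    ok = False
                    break
                del chain[len(chain) - k:]
                pos = chain[-1]
        if ok and len(chain) == n_beads:
            return np.asarray(chain)
    raise GenerationError(f"could not pack {n_beads} beads into ellipsoid {a}")


def _semi_axes(n_beads, aspect, target_rg=None):
    """Ellipsoid semi-axes for a domain of ``n_beads`` residues.

    Volume fixed at ``n_beads * VOLUME_PER_RESIDUE`` unless ``target_rg`` is
    given, in which case the axes are scaled so the uniform-ellipsoid Rg
    (sqrt((a^2+b^2+c^2)/5)) matches it.
    """
    aspect = np.asarray(aspect, dtype=float)
    if np.any(aspect <= 0):
        raise ValidationError("shape aspect ratios must be positive")
    vol = n_beads * VOLUME_PER_RESIDUE
    scale = (3.0 * vol / (4.0 * np.pi * np.prod(aspect))) ** (1.0 / 3.0)
    axes = aspect * scale
    if target_rg is not None:
        if target_rg <= 0:
            raise ValidationError("target_rg must be positive")
        rg0 = np.sqrt((axes ** 2).sum() / 5.0)
        axes = axes * (target_rg / rg0)
    return axes


def _groove_path(coords_a, n_points, rng=None):
    """Groove target points: an arc hugging the domain-A surface.

    The arc starts one bond above the chain-exit bead (the last domain-A bead,
    which generation places on the surface) and follows a sphere of radius
    ``r_exit + GROOVE_STANDOFF`` around the domain centroid.
    """
    c = coords_a.mean(axis=0)
    exit_bead = coords_a[-1]
    u = exit_bead - c
    r_exit = np.linalg.norm(u)
    u = u / r_exit
    # deterministic tangential direction
    ref = np.array([0.0, 1.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    v = ref - (ref @ u) * u
    v = v / np.linalg.norm(v)
    if rng is not None:
        ang = rng.uniform(0, 2 * np.pi)
        w = np.cross(u, v)
        v = np.cos(ang) * v + np.sin(ang) * w
    radius = r_exit + GROOVE_STANDOFF
    dphi = 2.0 * np.arcsin(0.5 * BOND_LENGTH / radius)
    phis = dphi * np.arange(1, n_points + 1)
    return c + radius * (np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * v)


def _grow_tracked_chain(start, targets, rng, obstacles, tol=2.6, max_retries=400):
    """Grow a 3.8 A chain whose bead j lands within ``tol`` of targets[j]."""
    for attempt in range(max_retries):
        chain = []
        pos = np.asarray(start, dtype=float)
        noise = 0.5 + 0.15 * attempt
        ok = True
        for j, t in enumerate(targets):
            placed = False
            for _ in range(60):
                d = (t - pos) + rng.normal(scale=noise, size=3)
                nd = np.linalg.norm(d)
                if nd < 1e-9:
                    continue
                cand = pos + BOND_LENGTH * d / nd
                if np.linalg.norm(cand - t) > tol:
                    continue
                if _clashes(cand, obstacles, skip_last=j == 0):
                    continue
                if len(chain) >= 2 and _clashes(cand, np.asarray(chain)):
                    continue
                chain.append(cand)
                pos = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(chain)
    raise GenerationError("groove-tracked chain growth failed", max_retries)


def _attach_rigid(body_rel, anchor, rng, obstacles, max_retries=300):
    """Place a rigid bead body whose first bead bonds to ``anchor``."""
    from scipy.spatial.transform import Rotation

    for _ in range(max_retries):
        u = _random_unit(rng)[0]
        first = anchor + BOND_LENGTH * u
        if _clashes(first, obstacles, skip_last=True):
            continue
        rot = Rotation.random(rng=rng).as_matrix()
        body = first + body_rel @ rot.T
        d = cdist(body, obstacles)
        d[0, -1] = np.inf  # bonded pair
        if (d < MIN_DIST).any():
            continue
        return body
    raise GenerationError("rigid-body attachment failed", max_retries)


# ---------------------------------------------------------------------------
# public operations


def build_domain_fixture(n_residues_a, n_residues_b, linker_length,
                         shape_params=None, seed=0):
    """Build the reference conformer: two compact domains plus a linker.

    ``shape_params`` keys (all optional): ``aspect_a``, ``aspect_b`` (semi-axis
    ratios), ``target_rg_a``, ``target_rg_b`` (override the density-derived
    size).  Domains are self-avoiding chains packed into quasi-ellipsoids at
    ~1 bead / 110 Da density; the linker is left in an arbitrary valid OPEN
    pose.  Deterministic for a fixed seed.

    In test mode ``n_residues_b=0`` is allowed and yields a single-domain
    conformer (no linker reference semantics beyond placement).
    """
    sp = dict(shape_params or {})
    aspect_a = sp.get("aspect_a", (1.3, 1.0, 0.85))
    aspect_b = sp.get("aspect_b", (1.2, 1.0, 0.9))
    if n_residues_a < 10:
        raise ValidationError("n_residues_a must be >= 10")
    if n_residues_b != 0 and n_residues_b < 10:
        raise ValidationError("n_residues_b must be >= 10 (or 0 in test mode)")
    if n_residues_b > 0 and linker_length < 2:
        raise ValidationError("linker_length must be >= 2")

    rng = np.random.default_rng(seed)
    axes_a = _semi_axes(n_residues_a, aspect_a, sp.get("target_rg_a"))
    coords_a = _grow_compact_cluster(n_residues_a, axes_a, rng)[::-1].copy()
    # reversed: the generation start (surface bead) becomes the chain exit
    coords_a -= coords_a.mean(axis=0)

    if n_residues_b == 0:
        segs = np.array([DOMAIN_A] * n_residues_a)
        return Conformer(coords_a, segs, OPEN, 0, 0, "fixture",
                         meta={"single_domain": True, "seed": seed})

    hinge_len = min(HINGE_LEN, linker_length - 1)
    n_link = linker_length - hinge_len
    segs = np.array([DOMAIN_A] * n_residues_a + [LINKER] * n_link +
                    [HINGE] * hinge_len + [DOMAIN_B] * n_residues_b)

    axes_b = _semi_axes(n_residues_b, aspect_b, sp.get("target_rg_b"))
    coords_b = _grow_compact_cluster(n_residues_b, axes_b, rng)
    body_rel = coords_b - coords_b[0]

    groove = _groove_path(coords_a, n_link)
    ref_linker = n_residues_a + n_link - 1
    ref_groove = int(np.argmin(np.linalg.norm(coords_a - groove[-1], axis=1)))

    # arbitrary valid OPEN pose for the full linker + domain B
    for _ in range(50):
        try:
            linker = _grow_free_chain(coords_a[-1], linker_length, rng, coords_a)
            obstacles = np.vstack([coords_a, linker])
            body = _attach_rigid(body_rel, linker[-1], rng, obstacles)
            break
        except GenerationError:
            continue
    else:
        raise GenerationError("fixture assembly failed")

    coords = np.vstack([coords_a, linker, body])
    conf = Conformer(coords, segs, OPEN, ref_linker, ref_groove, "fixture",
                     meta={"seed": seed, "groove_path": groove,
                           "axes_a": axes_a, "axes_b": axes_b})
    conf.validate_geometry()
    return conf


def sample_conformer(reference, mode, seed, extension_bias=0.0, conf_id=None):
    """Resample the flexible parts of ``reference`` in a given linker mode.

    mode "IN": the non-hinge linker beads track the groove path on domain A
    (so the linker reference bead ends within ``GROOVE_CONTACT`` of the groove
    reference bead); only the hinge and domain-B placement are random.
    mode "OUT": the whole linker is regrown as a self-avoiding random chain;
    ``extension_bias`` > 0 adds directional persistence (more extended poses).
    """
    mode = mode.upper()
    if mode not in ("IN", "OUT"):
        raise ValidationError(f"mode must be IN or OUT, got {mode!r}")
    if reference.meta.get("single_domain"):
        raise ValidationError("reference lacks a second domain")
    rng = np.random.default_rng(seed)
    segs = reference.segments
    idx_a = np.flatnonzero(segs == DOMAIN_A)
    idx_b = np.flatnonzero(segs == DOMAIN_B)
    n_link = int((segs == LINKER).sum())
    n_hinge = int((segs == HINGE).sum())
    coords_a = reference.coords[idx_a]
    body_rel = reference.coords[idx_b] - reference.coords[idx_b[0]]
    groove = reference.meta.get("groove_path")
    if mode == "IN" and groove is None:
        raise ValidationError("reference has no groove path (required for IN)")

    last_err = None
    for _ in range(80):
        try:
            if mode == "IN":
                bound = _grow_tracked_chain(coords_a[-1], groove[:n_link], rng,
                                            coords_a)
                obstacles = np.vstack([coords_a, bound])
                hinge = _grow_free_chain(bound[-1], n_hinge, rng, obstacles)
                linker = np.vstack([bound, hinge])
            else:
                linker = _grow_free_chain(coords_a[-1], n_link + n_hinge, rng,
                                          coords_a, bias=extension_bias)
            obstacles = np.vstack([coords_a, linker])
            body = _attach_rigid(body_rel, linker[-1], rng, obstacles)
            coords = np.vstack([coords_a, linker, body])
            state = BOUND if mode == "IN" else OPEN
            conf = Conformer(coords, segs, state, reference.ref_linker_bead,
                             reference.ref_groove_bead,
                             conf_id if conf_id is not None else f"{mode}-{seed}",
                             meta={"seed": seed, "mode": mode})
            if mode == "IN" and conf.d_rm() > GROOVE_CONTACT:
                raise GenerationError("bound linker drifted off the groove")
            return conf
        except GenerationError as err:
            last_err = err
            continue
    raise GenerationError(
        f"sampling failed after 80 restarts: {last_err}",
        getattr(last_err, "retries", 0))


def build_pool(reference, n_in, n_out, seed, extension_bias=0.0):
    """Pool of exactly ``n_in`` BOUND and ``n_out`` OPEN conformers."""
    if n_in < 0 or n_out < 0 or n_in + n_out < 1:
        raise ValidationError("need n_in + n_out >= 1")
    rng = np.random.default_rng(seed)
    members = []
    failures = []
    for i in range(n_in):
        sub = int(rng.integers(0, 2 ** 31))
        try:
            members.append(sample_conformer(reference, "IN", sub,
                                            conf_id=f"in-{i:05d}"))
        except GenerationError as err:
            failures.append((f"in-{i:05d}", str(err)))
    for i in range(n_out):
        sub = int(rng.integers(0, 2 ** 31))
        try:
            members.append(sample_conformer(reference, "OUT", sub,
                                            extension_bias=extension_bias,
                                            conf_id=f"out-{i:05d}"))
        except GenerationError as err:
            failures.append((f"out-{i:05d}", str(err)))
    if failures:
        raise GenerationError(
            f"pool generation aborted: {len(failures)} member(s) failed; "
            f"partial pool had {len(members)} members; first failure: "
            f"{failures[0]}")
    mode = "MIXED" if (n_in > 0 and n_out > 0) else ("IN" if n_in else "OUT")
    prov = {"mode": mode, "seed": seed, "n_in": n_in, "n_out": n_out,
            "extension_bias": extension_bias}
    return ConformerPool(members, provenance=prov)


def _pool_features(pool):
    """Per-member features: domain-B COM in the domain-A frame, plus d_RM."""
    from .metrics import superpose_on_segment

    ref = pool.members[0]
    feats = np.empty((pool.size, 4))
    for i, m in enumerate(pool.members):
        aligned = superpose_on_segment(m, ref, DOMAIN_A)
        com_b = aligned[m.segments == DOMAIN_B].mean(axis=0)
        feats[i, :3] = com_b
        feats[i, 3] = m.d_rm()
    return feats


def cluster_pool(pool, k, seed):
    """k representative members (nearest to each k-means centroid).

    Features: the domain-B center of mass expressed in the domain-A frame and
    the linker/groove reference distance d_RM.
    """
    from sklearn.cluster import KMeans

    if k > pool.size:
        raise ValidationError(f"k={k} exceeds pool size {pool.size}")
    if k == pool.size:
        reps = list(range(pool.size))
    else:
        feats = _pool_features(pool)
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(feats)
        reps = []
        for c in range(k):
            in_c = np.flatnonzero(labels == c)
            if len(in_c) == 0:
                continue
            d = np.linalg.norm(feats[in_c] - km.cluster_centers_[c], axis=1)
            reps.append(int(in_c[np.argmin(d)]))
        reps = sorted(set(reps))
    prov = dict(pool.provenance)
    prov.update({"clustered_from": pool.size, "k": k, "cluster_seed": seed})
    return ConformerPool([pool.members[i] for i in reps], provenance=prov)


# ---------------------------------------------------------------------------
# persistence: CA-only PDB + JSON sidecar, pools as directory + manifest


def write_conformer(conf, path):
    """Write a conformer as a CA-only PDB file plus a JSON sidecar.

    Segment labels are encoded in the chain ID; linker state, reference beads
    and id go in ``<path>.json``.
    """
    lines = []
    for i, (xyz, seg) in enumerate(zip(conf.coords, conf.segments)):
        lines.append(
            "ATOM  {serial:>5d}  CA  GLY {chain}{resi:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
            " C  ".format(serial=i + 1, chain=_CHAIN_ID[str(seg)],
                          resi=i + 1, x=xyz[0], y=xyz[1], z=xyz[2],
                          occ=1.0, b=0.0))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    sidecar = {
        "id": conf.id,
        "linker_state": conf.linker_state,
        "ref_linker_bead": int(conf.ref_linker_bead),
        "ref_groove_bead": int(conf.ref_groove_bead),
    }
    if "groove_path" in conf.meta:
        sidecar["groove_path"] = np.asarray(conf.meta["groove_path"]).tolist()
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_conformer(path):
    coords = []
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            chain = line[21]
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
            segs.append(_SEG_FROM_CHAIN[chain])
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    meta = {}
    if "groove_path" in sidecar:
        meta["groove_path"] = np.asarray(sidecar["groove_path"])
    return Conformer(np.asarray(coords), np.asarray(segs),
                     sidecar["linker_state"], sidecar["ref_linker_bead"],
                     sidecar["ref_groove_bead"], sidecar["id"], meta=meta)


def write_pool(pool, directory):
    os.makedirs(directory, exist_ok=True)
    filenames = []
    for i, m in enumerate(pool.members):
        fn = f"conf_{i:05d}.pdb"
        write_conformer(m, os.path.join(directory, fn))
        filenames.append(fn)
    manifest = {"size": pool.size, "files": filenames,
                "ids": pool.ids(),
                "provenance": _jsonable(pool.provenance)}
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_pool(directory):
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    members = [read_conformer(os.path.join(directory, fn))
               for fn in manifest["files"]]
    return ConformerPool(members, provenance=manifest.get("provenance", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
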