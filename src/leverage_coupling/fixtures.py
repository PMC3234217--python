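"""Synthetic test structures: toy two-mode globules, pocket-bearing clusters,
and self-avoiding Cα chains.

These generators make the full pipeline testable without downloading any
real structure.  The toy system realizes the canonical thought experiment of
leverage coupling: a globule with four concave binding sites W, X, Y, Z and
two designed orthonormal motions — a "green" mode that opens site X while
closing site Z, and a "red" mode that deforms X and closes Y — so that the
pairs (X, Z) and (X, Y) are strongly coupled while every pair involving W,
and the pair (Z, Y), are weakly coupled.  The toy bypasses the elastic
network on purpose: the coupling formalism is mode-agnostic, and injecting
designed modes isolates docking + leverage + coupling from ENM idiosyncrasy.

Geometry presets are frozen; only the seed varies between runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm import ModeSet
from .structure import CAStructure, Site

# frozen geometry presets (Å)
LATTICE_SPACING = 4.6      # bead spacing in the globule lattice
LATTICE_JITTER = 0.25      # positional jitter to break lattice degeneracy
POCKET_RADIUS = 5.2        # carved-channel radius (toy pockets)
POCKET_MOUTH_RADIUS = 6.2  # carved-channel radius (single-pocket fixture)
MIN_SEPARATION = 3.5       # hard-core between beads
SITE_RADIUS = 8.0          # beads within this of a pocket centre line it


def _jittered_ball(n: int, rng: np.random.Generator, carve_axes, pocket_depth: float):
    """n beads of a jittered cubic lattice filling a ball, with one
    cylindrical pocket carved along each unit vector in ``carve_axes``."""
    a = LATTICE_SPACING
    # generous candidate ball, trimmed to n beads closest to the origin
    half = int(np.ceil((n ** (1 / 3)) * 2 + 4))
    grid = np.arange(-half, half + 1) * a
    pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
    pts = pts + rng.uniform(-LATTICE_JITTER, LATTICE_JITTER, pts.shape)
    order = np.argsort(np.linalg.norm(pts, axis=1))
    pts = pts[order]

    outer = np.linalg.norm(pts[n - 1])  # radius holding n beads pre-carve
    keep = np.ones(len(pts), dtype=bool)
    axes = []
    for axis in carve_axes:
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        z = pts @ axis
        rho = np.linalg.norm(pts - z[:, None] * axis, axis=1)
        keep &= ~((rho < POCKET_RADIUS) & (z > outer - pocket_depth))
        axes.append(axis)
    pts = pts[keep]
    if len(pts) < n:
        raise ValueError(
            f"infeasible geometry: only {len(pts)} beads survive carving, "
            f"{n} requested"
        )
    pts = pts[np.argsort(np.linalg.norm(pts, axis=1))][:n]
    # stable, chain-like ordering: sweep along z, serpentine in y
    idx = np.lexsort((pts[:, 0], pts[:, 1], np.round(pts[:, 2] / a)))
    pts = pts[idx]

    # pocket centre = the probe position on the channel axis seeing the most
    # beads in the attractive well [5.5, 8] Å without hard-core clashes
    centers = []
    for axis in axes:
        best, best_score = None, -1
        for z in np.arange(outer - pocket_depth, outer + 2.0, 0.25):
            c = axis * z
            d = np.linalg.norm(pts - c, axis=1)
            if d.min() < 4.6:
                continue
            score = int(((d >= 5.5) & (d <= 8.0)).sum())
            if score > best_score:
                best, best_score = c, score
        if best is None:
            raise ValueError("infeasible geometry: no clash-free pocket centre")
        centers.append(best)
    return pts, centers


def _as_structure(coords: np.ndarray) -> CAStructure:
    m = len(coords)
    return CAStructure(
        residue_ids=[("A", i + 1, "") for i in range(m)],
        coords=coords,
        labels=["ALA"] * m,
    )


@dataclass
class PocketSystem:
    """A globular cluster with one concave pocket, plus labeled residue sets
    and the reference probe position at the pocket centre."""

    structure: CAStructure
    pocket_lining: frozenset[int]
    convex_surface: frozenset[int]
    pocket_center: np.ndarray


def _fibonacci_shell(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n near-uniform points on a sphere (Fibonacci lattice, small jitter)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    pts = radius * np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )
    return pts + rng.uniform(-0.15, 0.15, pts.shape)


def make_pocket_structure(
    n_residues: int = 100, pocket_depth: float = 9.0, seed: int = 0
) -> PocketSystem:
    """Sphere-like bead cluster with one carved pocket of the stated depth.

    Beads sit on concentric Fibonacci shells (spacing ≈ one lattice
    constant) so the outer surface is smooth and convex except for one
    cylindrical pocket carved along +z.  ``pocket_lining`` are the beads
    within 8 Å of the pocket-centre probe position; ``convex_surface`` are
    outer-shell beads of the opposite hemisphere (the pocket-free control
    surface).
    """
    if n_residues < 30:
        raise ValueError("n_residues must be >= 30")
    if pocket_depth <= 0:
        raise ValueError("pocket_depth must be positive")
    rng = np.random.default_rng(seed)
    a = LATTICE_SPACING
    coords = None
    for R in np.arange(9.0, 40.0, 0.25):
        if pocket_depth >= R:
            continue
        radii = list(np.arange(R, 3.7, -(a - 0.2)))
        counts = [max(int(round(4.0 * np.pi * r * r / a**2)), 6) for r in radii]
        pts = np.vstack([
            _fibonacci_shell(c, r, rng) for c, r in zip(counts, radii)
        ])
        rho = np.linalg.norm(pts[:, :2], axis=1)
        survivors = pts[
            ~((rho < POCKET_MOUTH_RADIUS) & (pts[:, 2] > R - pocket_depth))
        ]
        if len(survivors) >= n_residues:
            # trim from the inside out, but protect the slab under the
            # pocket floor so the pocket stays closed
            rr = np.linalg.norm(survivors, axis=1)
            floor = (
                (np.linalg.norm(survivors[:, :2], axis=1) < 9.0)
                & (survivors[:, 2] > R - pocket_depth - 5.0)
            )
            idx = np.sort(np.argsort(-(rr + 100.0 * floor))[:n_residues])
            coords = survivors[idx]
            outer = R
            break
    if coords is None:
        raise ValueError(
            f"infeasible geometry: no globule of {n_residues} beads fits a "
            f"{pocket_depth} Å pocket"
        )
    st = _as_structure(coords)

    # pocket-centre probe position: axis point with the most beads in the
    # attractive well and no hard-core clash
    center, best_score = None, -1
    for z in np.arange(outer - pocket_depth, outer + 2.0, 0.25):
        c = np.array([0.0, 0.0, z])
        d = np.linalg.norm(coords - c, axis=1)
        if d.min() < 4.6:
            continue
        score = int(((d >= 5.5) & (d <= 8.0)).sum())
        if score > best_score:
            center, best_score = c, score
    if center is None:
        raise ValueError("infeasible geometry: no clash-free pocket centre")

    d_center = np.linalg.norm(coords - center, axis=1)
    lining = frozenset(np.nonzero(d_center <= SITE_RADIUS)[0].tolist())
    if not lining:
        raise ValueError("infeasible geometry: pocket has no lining residues")

    rr = np.linalg.norm(coords, axis=1)
    convex = frozenset(
        np.nonzero((rr > outer - 2.2) & (coords[:, 2] < 0))[0].tolist()
    )
    return PocketSystem(
        structure=st,
        pocket_lining=lining,
        convex_surface=convex,
        pocket_center=center,
    )


@dataclass
class ToySystem:
    """The four-site, two-mode toy globule with its qualitative truth."""

    structure: CAStructure
    designed_modes: ModeSet
    sites: dict[str, Site]
    truth: dict[str, list[tuple[str, str]]]


def _gaussian_weight(coords: np.ndarray, axis: np.ndarray, sigma_deg: float):
    """Angular-Gaussian weight of each bead around a pocket axis."""
    r = np.linalg.norm(coords, axis=1)
    cosang = np.clip((coords @ axis) / np.maximum(r, 1e-9), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return np.exp(-0.5 * (ang / sigma_deg) ** 2)


def make_toy_two_mode_system(seed: int = 0, n_residues: int = 84) -> ToySystem:
    """Globule with four concave sites and two designed orthonormal modes.

    The "green" mode moves site-X beads radially outward (opening) and
    site-Z beads inward (closing); the "red" mode stretches site X
    tangentially (an elliptic pocket deformation) and closes site Y.  Site
    W is left undeformed by both.  Fields are Gram–Schmidt orthonormalized.
    The expected coupling order — D_XY and D_XZ exceed all couplings
    involving W and the pair (Z, Y) — is recorded in ``truth``.
    """
    rng = np.random.default_rng(seed)
    # tetrahedral pocket directions
    axes = {
        "W": np.array([1.0, 1.0, 1.0]) / np.sqrt(3),
        "X": np.array([1.0, -1.0, -1.0]) / np.sqrt(3),
        "Y": np.array([-1.0, 1.0, -1.0]) / np.sqrt(3),
        "Z": np.array([-1.0, -1.0, 1.0]) / np.sqrt(3),
    }
    coords, centers = _jittered_ball(
        n_residues, rng, list(axes.values()), pocket_depth=7.0
    )
    st = _as_structure(coords)

    # site members: beads near the pocket centre AND within 45° of the
    # pocket axis — the angular gate keeps core beads (which probes in
    # *other* pockets can reach) out of the labeled sites
    r = np.linalg.norm(coords, axis=1)
    sites = {}
    for (name, axis), c in zip(axes.items(), centers):
        ang = np.degrees(
            np.arccos(np.clip((coords @ axis) / np.maximum(r, 1e-9), -1.0, 1.0))
        )
        members = frozenset(
            np.nonzero(
                (np.linalg.norm(coords - c, axis=1) <= SITE_RADIUS) & (ang < 45.0)
            )[0].tolist()
        )
        sites[name] = Site(name=name, members=members)

    r = np.linalg.norm(coords, axis=1)
    rhat = coords / np.maximum(r, 1e-9)[:, None]
    sigma = 30.0  # deg, site-deformation falloff

    def radial(site_axis):
        return _gaussian_weight(coords, site_axis, sigma)[:, None] * rhat

    def elliptic(site_axis):
        # stretch along one tangent axis, compress along the other
        e1 = np.cross(site_axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(site_axis, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(site_axis, e1)
        p = coords - (coords @ site_axis)[:, None] * site_axis
        w = _gaussian_weight(coords, site_axis, sigma)[:, None]
        field = (p @ e1)[:, None] * e1 - (p @ e2)[:, None] * e2
        scale = np.maximum(np.linalg.norm(field, axis=1).max(), 1e-9)
        return w * field / scale

    # amplitudes chosen so X is the most-deformed site under both modes
    green = 1.0 * radial(axes["X"]) - 0.8 * radial(axes["Z"])
    red = 2.2 * elliptic(axes["X"]) - 0.6 * radial(axes["Y"])

    # Gram–Schmidt orthonormalization over the flattened fields
    g = green.ravel() / np.linalg.norm(green)
    rflat = red.ravel()
    rflat = rflat - (rflat @ g) * g
    rflat /= np.linalg.norm(rflat)
    vectors = np.stack([g.reshape(-1, 3), rflat.reshape(-1, 3)])

    modes = ModeSet(
        vectors=vectors,
        eigenvalues=np.array([1.0, 2.0]),  # placeholder ranks; shapes matter
        trivial_count=0,
    )
    truth = {
        "coupled": [("X", "Y"), ("X", "Z")],
        "weak": [("X", "W"), ("Z", "Y"), ("Z", "W"), ("Y", "W")],
    }
    return ToySystem(structure=st, designed_modes=modes, sites=sites, truth=truth)


def make_random_ca_chain(n: int, seed: int = 0) -> CAStructure:
    """Self-avoiding random walk with 3.8 Å steps; no non-adjacent pair
    closer than 4.0 Å."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    step = 3.8
    pts = [np.zeros(3)]
    attempts = 0
    while len(pts) < n:
        v = rng.normal(size=3)
        cand = pts[-1] + step * v / np.linalg.norm(v)
        prior = np.array(pts[:-1]) if len(pts) > 1 else None
        if prior is None or (np.linalg.norm(prior - cand, axis=1) >= 4.0).all():
            pts.append(cand)
            attempts = 0
        else:
            attempts += 1
            if attempts > 500:  # backtrack out of a dead end
                pts.pop()
                attempts = 0
    return _as_structure(np.array(pts))
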