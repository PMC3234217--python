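"""Coarse-grained Monte-Carlo docking of a flexible Cα-peptide probe.

The protein is completely rigid; a freely moving probe — a chain of
``probe_size`` pseudo-Cα atoms bonded at 3.8 Å — explores its surface under
a square-well potential: probe–protein (and non-bonded probe–probe)
distances below 4.5 Å are forbidden, and each probe-atom/residue pair at a
distance in [5.5, 8] Å contributes −ε (ε = 1, which sets the temperature
scale).  Each short simulated-annealing run yields one *probe location*:
the set of residues interacting with the probe at its endpoint — a
candidate binding site.

All randomness derives from a master seed via per-simulation
``numpy`` SeedSequence spawning, so runs are reproducible and
order-independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .structure import CAStructure

log = logging.getLogger(__name__)

HARD_CORE = 4.5   # Å, forbidden below this
WELL_MIN = 5.5    # Å, attractive well inner edge
WELL_MAX = 8.0    # Å, attractive well outer edge
BOND_LENGTH = 3.8  # Å, virtual Cα–Cα bond within the probe
EPSILON = 1.0     # well depth, defines the energy/temperature unit
WALL_MARGIN = 15.0  # Å, reflecting simulation boundary beyond the bounding
                    # radius: moves past it are rejected so an unbound probe
                    # stays near the protein and can re-bind


@dataclass
class DockingParams:
    """Monte-Carlo docking run parameters.

    ``probe_size`` is the number of probe atoms; ``n_sims`` the number of
    simulations (= probe locations generated) and ``n_steps`` the MC steps
    per simulation.  Annealing is geometric from ``t_start`` to ``t_end``
    (well units).  Move amplitudes: ``max_translation`` (Å),
    ``max_rotation`` and ``max_pivot`` (rad).
    """

    probe_size: int = 4
    n_steps: int = 5000
    n_sims: int = 100
    seed: int = 0
    t_start: float = 2.0
    t_end: float = 0.2
    max_translation: float = 1.5
    max_rotation: float = 0.4
    max_pivot: float = 0.4

    def __post_init__(self) -> None:
        if self.probe_size < 1:
            raise ValueError("probe_size must be >= 1")
        if self.n_steps < 1 or self.n_sims < 1:
            raise ValueError("n_steps and n_sims must be >= 1")
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")


@dataclass
class ProbeLocation:
    """Endpoint of one docking simulation.

    ``residues`` is the interacting-residue set (internal indices):
    residues within [5.5, 8] Å of any probe atom.  ``mode_leverages``
    (filled in by the leverage stage) holds L_Pμ per mode.
    """

    probe_coords: np.ndarray
    residues: frozenset[int]
    sim_index: int
    final_energy: float
    mode_leverages: np.ndarray | None = field(default=None, compare=False)


def probe_energy(
    structure: CAStructure, probe_coords: np.ndarray
) -> tuple[float, bool, int]:
    """Square-well energy of a probe configuration.

    Returns ``(energy, feasible, contacts)``: infeasible if any
    probe–protein or non-bonded probe–probe distance is below 4.5 Å;
    ``contacts`` counts (probe atom, residue) pairs in the attractive well
    [5.5, 8] Å; ``energy = −ε·contacts``.
    """
    probe = np.asarray(probe_coords, dtype=float).reshape(-1, 3)
    diff = probe[:, None, :] - structure.coords[None, :, :]
    d2 = np.einsum("pij,pij->pi", diff, diff)
    if (d2 < HARD_CORE**2).any():
        return 0.0, False, 0
    p = len(probe)
    if p > 2:
        pd = probe[:, None, :] - probe[None, :, :]
        pd2 = np.einsum("pqi,pqi->pq", pd, pd)
        iu = np.triu_indices(p, k=2)  # non-bonded pairs only
        if (pd2[iu] < HARD_CORE**2).any():
            return 0.0, False, 0
    contacts = int(((d2 >= WELL_MIN**2) & (d2 <= WELL_MAX**2)).sum())
    return -EPSILON * contacts, True, contacts


def interacting_residues(
    structure: CAStructure, probe_coords: np.ndarray
) -> frozenset[int]:
    """Residues within the attractive well of any probe atom."""
    probe = np.asarray(probe_coords, dtype=float).reshape(-1, 3)
    diff = probe[:, None, :] - structure.coords[None, :, :]
    d2 = np.einsum("pij,pij->pi", diff, diff)
    mask = ((d2 >= WELL_MIN**2) & (d2 <= WELL_MAX**2)).any(axis=0)
    return frozenset(np.nonzero(mask)[0].tolist())


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _initial_probe(
    structure: CAStructure, probe_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Extended chain, random orientation, centroid on a sphere 10 Å
    outside the structure's bounding radius."""
    center = structure.coords.mean(axis=0)
    radius = structure.bounding_radius() + 10.0
    pos = center + radius * _random_unit_vector(rng)
    direction = _random_unit_vector(rng)
    offsets = (np.arange(probe_size) - (probe_size - 1) / 2.0)[:, None] * (
        BOND_LENGTH * direction
    )
    return pos + offsets


def sim_rng(master_seed: int, sim_index: int) -> np.random.Generator:
    """Per-simulation RNG stream, independent of scheduling order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(sim_index,))
    )


@njit(cache=True)
def _kernel_energy(coords, probe):
    """Square-well energy inside the MC kernel; mirrors probe_energy."""
    p = probe.shape[0]
    m = coords.shape[0]
    contacts = 0
    for a in range(p):
        for i in range(m):
            dx = probe[a, 0] - coords[i, 0]
            dy = probe[a, 1] - coords[i, 1]
            dz = probe[a, 2] - coords[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < HARD_CORE * HARD_CORE:
                return 0.0, False
            if WELL_MIN * WELL_MIN <= d2 <= WELL_MAX * WELL_MAX:
                contacts += 1
    for a in range(p):
        for b in range(a + 2, p):  # non-bonded probe pairs
            dx = probe[a, 0] - probe[b, 0]
            dy = probe[a, 1] - probe[b, 1]
            dz = probe[a, 2] - probe[b, 2]
            if dx * dx + dy * dy + dz * dz < HARD_CORE * HARD_CORE:
                return 0.0, False
    return -EPSILON * contacts, True


@njit(cache=True)
def _kernel_rotate(probe, lo, origin, axis, angle, out):
    """Rotate probe atoms lo..end about an axis through origin into out."""
    n = np.sqrt(axis[0] ** 2 + axis[1] ** 2 + axis[2] ** 2)
    x, y, z = axis[0] / n, axis[1] / n, axis[2] / n
    c = np.cos(angle)
    s = np.sin(angle)
    C = 1.0 - c
    for a in range(probe.shape[0]):
        if a < lo:
            out[a] = probe[a]
            continue
        px = probe[a, 0] - origin[0]
        py = probe[a, 1] - origin[1]
        pz = probe[a, 2] - origin[2]
        out[a, 0] = origin[0] + (c + x * x * C) * px + (x * y * C - z * s) * py + (x * z * C + y * s) * pz
        out[a, 1] = origin[1] + (y * x * C + z * s) * px + (c + y * y * C) * py + (y * z * C - x * s) * pz
        out[a, 2] = origin[2] + (z * x * C - y * s) * px + (z * y * C + x * s) * py + (c + z * z * C) * pz


@njit(cache=True)
def _mc_kernel(coords, probe, energy, kinds, trans, axes, angles, pivots,
               accept_u, temps, center, wall_radius):
    """Annealed Metropolis loop over pre-drawn random numbers."""
    n_steps = kinds.shape[0]
    p = probe.shape[0]
    trial = np.empty_like(probe)
    centroid = np.empty(3)
    for step in range(n_steps):
        kind = kinds[step]
        if kind == 0:
            for a in range(p):
                for d in range(3):
                    trial[a, d] = probe[a, d] + trans[step, d]
        elif kind == 1:
            for d in range(3):
                s = 0.0
                for a in range(p):
                    s += probe[a, d]
                centroid[d] = s / p
            _kernel_rotate(probe, 0, centroid, axes[step], angles[step], trial)
        else:
            pivot = pivots[step]
            _kernel_rotate(probe, pivot + 1, probe[pivot], axes[step], angles[step], trial)
        # reflecting wall: keep the probe centroid inside the simulation sphere
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for a in range(p):
            cx += trial[a, 0]
            cy += trial[a, 1]
            cz += trial[a, 2]
        cx = cx / p - center[0]
        cy = cy / p - center[1]
        cz = cz / p - center[2]
        if cx * cx + cy * cy + cz * cz > wall_radius * wall_radius:
            continue
        e_new, ok = _kernel_energy(coords, trial)
        if ok:
            de = e_new - energy
            if de <= 0.0 or accept_u[step] < np.exp(-de / temps[step]):
                for a in range(p):
                    for d in range(3):
                        probe[a, d] = trial[a, d]
                energy = e_new
    return energy


def run_docking_simulation(
    structure: CAStructure, params: DockingParams, sim_index: int
) -> ProbeLocation:
    """One annealed Metropolis docking run; deterministic in (seed, sim_index).

    Per step one move is drawn uniformly from {rigid translation, rigid
    rotation about the probe centroid, internal pivot about a random bond}
    (translation only for a one-atom probe).  Infeasible configurations
    (hard-core violations) are rejected outright.  The random stream for
    the whole run is drawn up front from the per-simulation generator and
    consumed by a compiled Metropolis loop.
    """
    rng = sim_rng(params.seed, sim_index)
    # a long extended probe centred just outside the bounding sphere can
    # still clash with the protein; resample until clash-free
    for _ in range(1000):
        probe = _initial_probe(structure, params.probe_size, rng)
        energy, feasible, _ = probe_energy(structure, probe)
        if feasible:
            break
    else:
        raise RuntimeError("could not place initial probe without clashes")

    n = params.n_steps
    n_moves = 3 if params.probe_size >= 2 else 1
    kinds = rng.integers(n_moves, size=n)
    trans = rng.uniform(-params.max_translation, params.max_translation, (n, 3))
    axes = rng.normal(size=(n, 3))
    # one angle per step, scaled per move kind
    raw = rng.uniform(-1.0, 1.0, n)
    angles = np.where(kinds == 1, raw * params.max_rotation, raw * params.max_pivot)
    pivots = rng.integers(max(1, params.probe_size - 1), size=n)
    accept_u = rng.random(n)
    if n > 1:
        ratio = (params.t_end / params.t_start) ** (1.0 / (n - 1))
    else:
        ratio = 1.0
    temps = params.t_start * ratio ** np.arange(n)

    center = structure.coords.mean(axis=0)
    wall_radius = structure.bounding_radius() + WALL_MARGIN
    energy = _mc_kernel(
        np.ascontiguousarray(structure.coords),
        probe, energy, kinds, trans, axes, angles, pivots, accept_u, temps,
        center, wall_radius,
    )

    final_energy, _, _ = probe_energy(structure, probe)
    return ProbeLocation(
        probe_coords=probe,
        residues=interacting_residues(structure, probe),
        sim_index=sim_index,
        final_energy=final_energy,
    )


def generate_probe_locations(
    structure: CAStructure, params: DockingParams
) -> list[ProbeLocation]:
    """Run ``n_sims`` docking simulations and keep the bound endpoints.

    Locations whose probe ended unbound (empty interacting-residue set) are
    dropped with a logged count.  The result is ordered by ``sim_index``.

    Raises
    ------
    RuntimeError
        If every simulation ended unbound — try longer runs or a lower
        final temperature.
    """
    kept: list[ProbeLocation] = []
    n_empty = 0
    for s in range(params.n_sims):
        loc = run_docking_simulation(structure, params, s)
        if loc.residues:
            kept.append(loc)
        else:
            n_empty += 1
        if (s + 1) % max(1, params.n_sims // 10) == 0:
            log.info("docking: %d/%d simulations done", s + 1, params.n_sims)
    if n_empty:
        log.info("docking: %d/%d probes ended unbound and were dropped",
                 n_empty, params.n_sims)
    if not kept:
        raise RuntimeError(
            "all probes ended unbound; increase n_steps or lower t_end"
        )
    return kept


def locations_to_jsonl(
    locations: list[ProbeLocation], structure: CAStructure, seed: int
) -> str:
    """Serialize probe locations as JSON-lines with author residue ids."""
    lines = []
    for loc in locations:
        rec = {
            "sim_index": loc.sim_index,
            "seed": seed,
            "residues": [
                ":".join(str(p) for p in structure.residue_ids[i] if p != "")
                for i in sorted(loc.residues)
            ],
            "residue_indices": sorted(loc.residues),
            "probe_coords": np.round(loc.probe_coords, 4).tolist(),
            "energy": loc.final_energy,
        }
        lines.append(json.dumps(rec))
    return "\n".join(lines) + "\n"


def locations_from_jsonl(text: str) -> list[ProbeLocation]:
    """Read probe locations written by :func:`locations_to_jsonl`."""
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        out.append(
            ProbeLocation(
                probe_coords=np.array(rec["probe_coords"], dtype=float),
                residues=frozenset(rec["residue_indices"]),
                sim_index=int(rec["sim_index"]),
                final_energy=float(rec["energy"]),
            )
        )
    return out
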