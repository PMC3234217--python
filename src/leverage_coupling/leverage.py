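"""Binding leverage: how strongly binding at a probe location resists a motion.

For a probe location P, springs are placed between residue pairs of P whose
interconnecting Cα–Cα segment passes through the bound probe.  The binding
leverage of P under mode μ is the total harmonic strain of those springs,

    L_Pμ = Σ_springs ½ k (Δd_ij)²,

with Δd_ij the linearized change of the i–j distance under the mode's
displacement field, Δd_ij = d̂_ij · (v_j − v_i).  The linearization makes
rigid-body modes carry exactly zero leverage and absorbs the (arbitrary)
mode amplitude into the overall leverage scale.

Per-residue leverages average L_Pμ over all probe locations containing the
residue:

    λ_iμ = Σ_P Δ_iP L_Pμ / Σ_P Δ_iP,

where Δ_iP indicates membership of residue i in location P.  The λ matrix
is the central object from which site couplings derive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .docking import ProbeLocation
from .enm import ModeSet
from .structure import CAStructure


@dataclass
class LeverageParams:
    """``k``: spring constant (arbitrary units).  ``pass_radius``: maximum
    point-to-segment distance (Å) for a residue-pair line to count as
    passing through the probe."""

    k: float = 1.0
    pass_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.pass_radius <= 0:
            raise ValueError("k and pass_radius must be positive")


@dataclass
class LeverageMatrix:
    """Per-residue, per-mode leverage λ_iμ (``lam``, shape (m, n), ≥ 0)
    with per-residue docking coverage Σ_P Δ_iP."""

    lam: np.ndarray
    coverage: np.ndarray
    mode_ids: list[int]

    @property
    def m(self) -> int:
        return self.lam.shape[0]

    @property
    def n(self) -> int:
        return self.lam.shape[1]


@dataclass
class ProfileSimilarityMatrix:
    """Mode–mode leverage-profile overlaps Λ_μν = Σ_i λ_iμ λ_iν and their
    cosine normalization Λ̂_μν ∈ [0, 1].  Λ_μμ ranks mode importance."""

    Lambda: np.ndarray
    normalized: np.ndarray


def _point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distances from each point to the segment a–b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def select_springs(
    structure: CAStructure,
    location: ProbeLocation,
    params: LeverageParams | None = None,
) -> list[tuple[int, int]]:
    """Residue pairs of a probe location whose Cα–Cα segment passes through
    the probe (within ``pass_radius`` of some probe atom)."""
    params = params or LeverageParams()
    if not location.residues:
        raise ValueError("probe location has no residues")
    members = sorted(location.residues)
    probe = location.probe_coords.reshape(-1, 3)
    pairs = []
    for a_i, i in enumerate(members):
        for j in members[a_i + 1 :]:
            d = _point_segment_distance(
                probe, structure.coords[i], structure.coords[j]
            )
            if (d <= params.pass_radius).any():
                pairs.append((i, j))
    return pairs


def probe_binding_leverage(
    structure: CAStructure,
    springs: list[tuple[int, int]],
    mode_vector: np.ndarray,
    params: LeverageParams | None = None,
) -> float:
    """Binding leverage L_Pμ = Σ ½ k (d̂_ij·(v_j − v_i))² over the springs."""
    params = params or LeverageParams()
    v = np.asarray(mode_vector, dtype=float).reshape(-1, 3)
    total = 0.0
    for i, j in springs:
        dvec = structure.coords[j] - structure.coords[i]
        dhat = dvec / np.linalg.norm(dvec)
        dd = float(dhat @ (v[j] - v[i]))
        total += 0.5 * params.k * dd * dd
    return total


def score_locations(
    structure: CAStructure,
    locations: list[ProbeLocation],
    modes: ModeSet,
    params: LeverageParams | None = None,
) -> list[ProbeLocation]:
    """Attach per-mode leverages L_Pμ to every probe location (in place)."""
    params = params or LeverageParams()
    for loc in locations:
        springs = select_springs(structure, loc, params)
        loc.mode_leverages = np.array(
            [
                probe_binding_leverage(structure, springs, modes.vectors[mu], params)
                for mu in range(modes.n)
            ]
        )
    return locations


def residue_leverage_matrix(
    locations: list[ProbeLocation], m: int, n_modes: int
) -> LeverageMatrix:
    """Average location leverages into the per-residue matrix λ_iμ.

    Residues covered by no probe location get λ = 0 by convention.
    """
    if not locations:
        raise ValueError("no probe locations given")
    lam_sum = np.zeros((m, n_modes))
    coverage = np.zeros(m)
    for loc in locations:
        if loc.mode_leverages is None:
            raise ValueError(
                f"location {loc.sim_index} has no per-mode leverages; "
                "run score_locations first"
            )
        idx = sorted(loc.residues)
        lam_sum[idx] += loc.mode_leverages[None, :]
        coverage[idx] += 1
    lam = np.zeros_like(lam_sum)
    covered = coverage > 0
    lam[covered] = lam_sum[covered] / coverage[covered, None]
    return LeverageMatrix(lam=lam, coverage=coverage, mode_ids=list(range(n_modes)))


def total_binding_leverage(lev: LeverageMatrix) -> np.ndarray:
    """Total binding leverage along the sequence: Σ_μ λ_iμ."""
    return lev.lam.sum(axis=1)


def profile_similarity(lev: LeverageMatrix) -> ProfileSimilarityMatrix:
    """Mode–mode overlap Λ_μν of the leverage profiles and its cosine
    normalization (pairs involving a zero profile get 0)."""
    Lambda = lev.lam.T @ lev.lam
    diag = np.diag(Lambda)
    denom = np.sqrt(np.outer(diag, diag))
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(denom > 0, Lambda / denom, 0.0)
    return ProfileSimilarityMatrix(Lambda=Lambda, normalized=normalized)


def leverage_to_tsv(lev: LeverageMatrix, structure: CAStructure) -> str:
    """TSV rendering: author residue ids, per-mode λ columns, coverage."""
    header = "residue\t" + "\t".join(f"mode{mu}" for mu in lev.mode_ids) + "\tcoverage"
    lines = [header]
    for i in range(lev.m):
        rid = ":".join(str(p) for p in structure.residue_ids[i] if p != "")
        row = "\t".join(f"{x:.10g}" for x in lev.lam[i])
        lines.append(f"{rid}\t{row}\t{int(lev.coverage[i])}")
    return "\n".join(lines) + "\n"
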