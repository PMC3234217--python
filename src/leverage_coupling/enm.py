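"""Cα elastic network models and their low-frequency normal modes.

The low-frequency eigenvectors of an elastic-network Hessian serve as the
independent conformational degrees of freedom of the analysis.  Two pair
force fields are provided:

``hinsen_calpha``
    The distance-dependent Cα pair potential of Hinsen et al.: a stiff
    linear regime for short (bonded-neighbour) distances and an r⁻⁶ decay
    beyond, applied to all residue pairs.  Constants (in kJ/mol/nm² with r
    in nm, converted internally to Å):
    ``k(r) = 8.6e2·r − 2.39e3`` for r < 4 Å, ``k(r) = 128e4·r⁻⁶`` beyond.
``cutoff_anm``
    Uniform springs between all pairs within a distance cutoff
    (default 15 Å) — the classic anisotropic network model, kept as a
    simple cross-checkable alternative.

Masses are uniform (unit): only mode shapes are consumed downstream and the
overall energy/frequency scale of the analysis is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .structure import CAStructure

# Hinsen Cα force-field constants converted to kJ/mol/Å² with r in Å
# (originals: 8.6e5·r − 2.39e5 kJ/mol/nm² for r < 0.4 nm; 128·r⁻⁶ kJ/mol/nm²
# beyond, r in nm).  Only ratios matter downstream.
_HINSEN_A = 860.0        # linear-regime slope, kJ/mol/Å³
_HINSEN_B = -2390.0      # linear-regime intercept, kJ/mol/Å²
_HINSEN_C = 1.28e6       # long-range amplitude, kJ/mol/Å²·Å⁶
_HINSEN_SWITCH = 4.0     # Å, regime boundary

ZERO_MODE_RTOL = 1e-8  # eigenvalue < rtol × max(eigenvalue) counts as trivial


@dataclass
class ENMParams:
    """Elastic-network parameters.

    ``force_field`` is ``"hinsen_calpha"`` or ``"cutoff_anm"``; ``cutoff``
    (Å) applies to the latter only.  ``spring_scale`` multiplies every
    spring constant (the absolute scale is arbitrary).  ``n_modes`` is the
    number of non-trivial low-frequency modes to keep (default 10).
    """

    force_field: str = "hinsen_calpha"
    cutoff: float = 15.0
    spring_scale: float = 1.0
    n_modes: int = 10

    def __post_init__(self) -> None:
        if self.force_field not in ("hinsen_calpha", "cutoff_anm"):
            raise ValueError(f"unknown force field {self.force_field!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")


@dataclass
class ModeSet:
    """Retained low-frequency normal modes.

    ``vectors`` has shape ``(n, m, 3)``; each mode is unit-normalized over
    all 3m components.  ``eigenvalues`` are ascending and strictly positive
    relative to the zero-mode tolerance.  ``trivial_vectors`` holds the
    discarded near-zero (rigid-body) modes, kept for diagnostics.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    trivial_count: int
    trivial_vectors: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    @property
    def m(self) -> int:
        return self.vectors.shape[1]


def pair_spring_constants(coords: np.ndarray, params: ENMParams) -> np.ndarray:
    """Symmetric (m, m) matrix of pair spring constants, zero diagonal."""
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    m = len(coords)
    k = np.zeros((m, m))
    if params.force_field == "hinsen_calpha":
        with np.errstate(divide="ignore", invalid="ignore"):
            short = _HINSEN_A * d + _HINSEN_B
            long_ = _HINSEN_C / d**6
        k = np.where(d < _HINSEN_SWITCH, np.maximum(short, 0.0), long_)
    else:  # cutoff_anm
        k = np.where(d <= params.cutoff, 1.0, 0.0)
    np.fill_diagonal(k, 0.0)
    return params.spring_scale * k


def network_energy(coords_flat: np.ndarray, ref: np.ndarray, k: np.ndarray) -> float:
    """Harmonic network energy Σ ½ k_ij (|r_ij| − |r⁰_ij|)² (for oracles)."""
    x = coords_flat.reshape(-1, 3)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    d0 = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    iu = np.triu_indices(len(ref), k=1)
    return float(0.5 * (k[iu] * (d[iu] - d0[iu]) ** 2).sum())


def build_hessian(structure: CAStructure, params: ENMParams | None = None) -> np.ndarray:
    """Assemble the 3m × 3m elastic-network Hessian.

    Off-diagonal 3×3 blocks are ``−k_ij · d̂d̂ᵀ`` with ``d̂`` the unit
    inter-bead vector; diagonal blocks make block-rows sum to zero, which
    enforces translational invariance exactly.

    Raises
    ------
    ValueError
        If the spring network is disconnected (lists component sizes).
    """
    params = params or ENMParams()
    if structure.m < 2:
        raise ValueError("need at least two residues for an elastic network")
    coords = structure.coords
    m = structure.m
    k = pair_spring_constants(coords, params)

    ncomp, labels = connected_components((k > 0).astype(int), directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"elastic network is disconnected: {ncomp} components "
            f"with sizes {sizes.tolist()}"
        )

    H = np.zeros((3 * m, 3 * m))
    ii, jj = np.nonzero(np.triu(k, k=1))
    for i, j in zip(ii, jj):
        dvec = coords[j] - coords[i]
        dist = np.linalg.norm(dvec)
        dhat = dvec / dist
        block = k[i, j] * np.outer(dhat, dhat)
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
    return H


def compute_modes(hessian: np.ndarray, params: ENMParams | None = None) -> ModeSet:
    """Diagonalize the Hessian and keep the lowest non-trivial modes.

    Modes with eigenvalue below ``ZERO_MODE_RTOL × λ_max`` are discarded as
    rigid-body (trivial) modes — six for any non-collinear structure.  The
    next ``n_modes`` are returned ascending by eigenvalue, each vector
    unit-normalized with its sign fixed so the largest-magnitude component
    is positive (reproducibility across linear-algebra backends).
    """
    params = params or ENMParams()
    w, v = scipy.linalg.eigh(hessian)
    tol = ZERO_MODE_RTOL * max(w[-1], 1.0e-300)
    trivial = int(np.sum(w < tol))
    n_avail = len(w) - trivial
    if n_avail < params.n_modes:
        raise ValueError(
            f"only {n_avail} non-trivial modes available, {params.n_modes} requested"
        )
    m3 = hessian.shape[0]
    m = m3 // 3

    def _fix(vec: np.ndarray) -> np.ndarray:
        vec = vec / np.linalg.norm(vec)
        imax = int(np.argmax(np.abs(vec)))
        return vec if vec[imax] > 0 else -vec

    sel = slice(trivial, trivial + params.n_modes)
    vectors = np.stack([_fix(v[:, i]).reshape(m, 3) for i in range(*sel.indices(m3))])
    trivial_vectors = np.stack(
        [_fix(v[:, i]).reshape(m, 3) for i in range(trivial)]
    ) if trivial else None
    return ModeSet(
        vectors=vectors,
        eigenvalues=w[sel].copy(),
        trivial_count=trivial,
        trivial_vectors=trivial_vectors,
    )


def compute_enm_modes(structure: CAStructure, params: ENMParams | None = None) -> ModeSet:
    """Convenience: build the Hessian and diagonalize in one call."""
    params = params or ENMParams()
    return compute_modes(build_hessian(structure, params), params)


def modes_to_tsv(modes: ModeSet) -> str:
    """Serialize a ModeSet as TSV (header carries eigenvalues)."""
    lines = ["# eigenvalues\t" + "\t".join(f"{e:.10g}" for e in modes.eigenvalues)]
    lines.append("residue\tmode\tdx\tdy\tdz")
    for mu in range(modes.n):
        for i in range(modes.m):
            dx, dy, dz = modes.vectors[mu, i]
            lines.append(f"{i}\t{mu}\t{dx:.10g}\t{dy:.10g}\t{dz:.10g}")
    return "\n".join(lines) + "\n"


def modes_from_tsv(text: str) -> ModeSet:
    """Inverse of :func:`modes_to_tsv` (trivial modes are not stored)."""
    lines = [l for l in text.splitlines() if l.strip()]
    eigenvalues = np.array([float(x) for x in lines[0].split("\t")[1:]])
    rows = [l.split("\t") for l in lines[2:]]
    m = max(int(r[0]) for r in rows) + 1
    n = max(int(r[1]) for r in rows) + 1
    vectors = np.zeros((n, m, 3))
    for r in rows:
        vectors[int(r[1]), int(r[0])] = [float(r[2]), float(r[3]), float(r[4])]
    return ModeSet(vectors=vectors, eigenvalues=eigenvalues, trivial_count=0)
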