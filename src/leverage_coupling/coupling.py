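"""Leverage coupling between sites: D_PQ, C_PQ, D_Pi and background.

A site P gets a leverage vector ℓ_P over the n modes, the mean of the λ
rows of its members:

    L_Pμ = (1/|P|) Σ_{i∈P} λ_iμ.

The leverage coupling between two sites is the scalar product
D_PQ = ℓ_P·ℓ_Q — large only if both sites have high leverage for the same
modes — and its cosine normalization C_PQ = D_PQ/√(D_PP·D_QQ) ∈ [0, 1]
compares coupling patterns independent of deformation magnitude.  Because
the absolute scale of leverage is arbitrary and protein-specific, site
couplings are judged against the *background*: the mean pairwise coupling
λ_i·λ_j among residues outside all annotated sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .leverage import LeverageMatrix
from .structure import Site


@dataclass
class SiteLeverageVector:
    """Per-mode leverage profile ℓ_P of one site (length n, nonnegative)."""

    site: str
    values: np.ndarray


@dataclass
class CouplingMatrix:
    """Site–site couplings: raw D (symmetric, ≥ 0), normalized C ∈ [0, 1],
    and the scalar background coupling."""

    names: list[str]
    D: np.ndarray
    C: np.ndarray
    background: float


def site_leverage_vector(lev: LeverageMatrix, site: Site) -> SiteLeverageVector:
    """Mean λ row over the site's members (the set norm is its size)."""
    members = site.sorted_members()
    if max(members) >= lev.m:
        raise ValueError(f"site {site.name!r} has members outside the structure")
    return SiteLeverageVector(site=site.name, values=lev.lam[members].mean(axis=0))


def leverage_coupling(p: SiteLeverageVector, q: SiteLeverageVector) -> float:
    """D_PQ = ℓ_P · ℓ_Q (symmetric, nonnegative)."""
    if p.values.shape != q.values.shape:
        raise ValueError(
            f"mode-count mismatch: {p.values.shape} vs {q.values.shape}"
        )
    return float(p.values @ q.values)


def normalized_coupling(D: np.ndarray) -> np.ndarray:
    """Cosine normalization C_PQ = D_PQ/√(D_PP·D_QQ); zero-leverage sites
    get C = 0 by convention."""
    D = np.asarray(D, dtype=float)
    diag = np.diag(D)
    denom = np.sqrt(np.outer(diag, diag))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, D / denom, 0.0)
    return np.clip(C, 0.0, 1.0)


def coupling_matrix(
    lev: LeverageMatrix, sites: list[Site], include_background: bool = True
) -> CouplingMatrix:
    """Full D and C matrices over a list of named sites."""
    if not sites:
        raise ValueError("no sites given")
    names = [s.name for s in sites]
    if len(set(names)) != len(names):
        raise ValueError("site names must be unique")
    vecs = np.stack([site_leverage_vector(lev, s).values for s in sites])
    D = vecs @ vecs.T
    C = normalized_coupling(D)
    bg = background_coupling(lev, sites) if include_background else float("nan")
    return CouplingMatrix(names=names, D=D, C=C, background=bg)


def site_residue_coupling(lev: LeverageMatrix, site: Site) -> np.ndarray:
    """D_Pi = ℓ_P · λ_i for every residue i (length m); shows how one site
    couples to the rest of the protein (used for surface coloring)."""
    ell = site_leverage_vector(lev, site).values
    return lev.lam @ ell


def background_coupling(lev: LeverageMatrix, sites: list[Site]) -> float:
    """Mean coupling λ_i·λ_j over unordered pairs of non-site residues."""
    in_site = np.zeros(lev.m, dtype=bool)
    for s in sites:
        in_site[s.sorted_members()] = True
    rows = lev.lam[~in_site]
    r = len(rows)
    if r == 0:
        raise ValueError("no residue outside the given sites")
    if r == 1:
        return 0.0
    G = rows @ rows.T
    iu = np.triu_indices(r, k=1)
    return float(G[iu].mean())


def single_mode_coupling(
    lev: LeverageMatrix, sites: list[Site], mode_id: int
) -> np.ndarray:
    """Coupling matrix from one mode only: D_PQ^(μ) = L_Pμ L_Qμ.

    Summed over all modes these rank-1 matrices reconstruct the full D
    exactly (bilinearity of the scalar product).
    """
    if not 0 <= mode_id < lev.n:
        raise ValueError(f"mode {mode_id} not in 0..{lev.n - 1}")
    vals = np.array(
        [site_leverage_vector(lev, s).values[mode_id] for s in sites]
    )
    return np.outer(vals, vals)


def matrix_to_tsv(names: list[str], M: np.ndarray) -> str:
    """TSV rendering of a named square matrix."""
    lines = ["site\t" + "\t".join(names)]
    for name, row in zip(names, np.asarray(M)):
        lines.append(name + "\t" + "\t".join(f"{x:.10g}" for x in row))
    return "\n".join(lines) + "\n"
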