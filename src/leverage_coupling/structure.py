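"""Cα bead-model structures, named residue sites, and PDB input/output.

The whole analysis runs on a fixed Cα representation of a protein: one bead
per amino-acid residue, identified by ``(chain, resnum, icode)`` exactly as
the structure file numbers it, and addressed internally by a contiguous
0-based index in file order.  Ligand heavy atoms (HETATM, non-water) are kept
alongside so that binding sites can be derived from ligand contacts.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

log = logging.getLogger(__name__)

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class CAStructure:
    """Ordered Cα bead model.

    Attributes
    ----------
    residue_ids:
        One ``(chain, resnum, icode)`` per bead, unique, in file order.
    coords:
        ``(m, 3)`` float array of Cα positions in Å.
    labels:
        Residue names (three-letter codes), one per bead.
    ligand_coords:
        ``(k, 3)`` array of ligand heavy-atom positions retained from HETATM
        records (k may be 0); not part of the bead model.
    ligand_names:
        Residue name of each retained ligand atom.
    """

    residue_ids: list[ResidueId]
    coords: np.ndarray
    labels: list[str]
    ligand_coords: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float)
    )
    ligand_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float).reshape(-1, 3)
        if len(self.residue_ids) != len(self.coords):
            raise ValueError(
                f"{len(self.residue_ids)} residue ids but {len(self.coords)} coordinates"
            )
        if self.m < 1:
            raise ValueError("structure must contain at least one residue")
        if len(set(self.residue_ids)) != self.m:
            raise ValueError("residue ids are not unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def m(self) -> int:
        """Number of residues (beads)."""
        return len(self.residue_ids)

    def index_of(self, chain: str, resnum: int, icode: str = "") -> int:
        """Internal index of a residue given its author identifiers."""
        try:
            return self.residue_ids.index((chain, int(resnum), icode))
        except ValueError:
            raise KeyError(
                f"residue {chain}:{resnum}{':' + icode if icode else ''} "
                "not in structure"
            ) from None

    def bounding_radius(self) -> float:
        """Radius of the structure around its centroid, Å."""
        c = self.coords.mean(axis=0)
        return float(np.linalg.norm(self.coords - c, axis=1).max())


@dataclass(frozen=True)
class Site:
    """A named set of residues (internal indices) on a structure."""

    name: str
    members: frozenset[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"site {self.name!r} has no members")
        if any(i < 0 for i in self.members):
            raise ValueError("negative residue index in site")

    def sorted_members(self) -> list[int]:
        return sorted(self.members)


def _parse_ranges(exclude_ranges) -> list[tuple[str | None, int, int]]:
    """Normalize exclusion ranges to (chain-or-None, lo, hi) inclusive."""
    out = []
    for r in exclude_ranges or []:
        if len(r) == 2:
            out.append((None, int(r[0]), int(r[1])))
        else:
            out.append((str(r[0]), int(r[1]), int(r[2])))
    return out


def read_ca_structure(
    pdb_text: str,
    chains: list[str] | None = None,
    exclude_ranges=None,
) -> CAStructure:
    """Read a Cα bead model from PDB-format text.

    One bead is taken per amino-acid residue with a Cα atom (first model
    only; highest-occupancy altloc, first on ties).  HETATM ligand heavy
    atoms (non-water, non-hydrogen) are retained separately for deriving
    sites from ligand contacts.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file.
    chains:
        Optional chain-id whitelist.
    exclude_ranges:
        Optional residue-number ranges to drop, each ``(lo, hi)`` (all
        chains) or ``(chain, lo, hi)``; bounds inclusive.

    Raises
    ------
    ValueError
        If no residue with a Cα atom survives the filters.
    """
    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    ranges = _parse_ranges(exclude_ranges)

    residue_ids: list[ResidueId] = []
    coords: list[np.ndarray] = []
    labels: list[str] = []
    lig_coords: list[np.ndarray] = []
    lig_names: list[str] = []

    if len(st) == 0:
        raise ValueError("no model in PDB input")
    model = st[0]  # MODEL 1 only: single-conformation method

    def _excluded(chain_id: str, resnum: int) -> bool:
        return any(
            (ch is None or ch == chain_id) and lo <= resnum <= hi
            for ch, lo, hi in ranges
        )

    for chain in model:
        for res in chain:
            resnum = res.seqid.num
            icode = (res.seqid.icode or " ").strip()
            is_water = res.name in _WATER_NAMES or res.is_water()
            ca_candidates = [a for a in res if a.name == "CA" and a.element.name == "C"]
            if res.het_flag != "H" or (ca_candidates and res.name not in _WATER_NAMES):
                # polymer residue: look for a Cα
                if chains is not None and chain.name not in chains:
                    continue
                if _excluded(chain.name, resnum):
                    continue
                if not ca_candidates:
                    if not is_water:
                        log.warning(
                            "residue %s %s:%d%s has no CA atom; skipped",
                            res.name, chain.name, resnum, icode,
                        )
                    continue
                ca = max(ca_candidates, key=lambda a: a.occ)
                residue_ids.append((chain.name, resnum, icode))
                coords.append(np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
                labels.append(res.name)
            elif not is_water:
                # ligand: keep heavy atoms for site derivation
                for a in res:
                    if a.element.name in ("H", "D"):
                        continue
                    lig_coords.append(np.array([a.pos.x, a.pos.y, a.pos.z]))
                    lig_names.append(res.name)

    if not residue_ids:
        filt = []
        if chains is not None:
            filt.append(f"chains={chains}")
        if ranges:
            filt.append(f"exclude_ranges={exclude_ranges}")
        raise ValueError(
            "no amino-acid residue with a CA atom found"
            + (f" after filters ({', '.join(filt)})" if filt else "")
        )

    return CAStructure(
        residue_ids=residue_ids,
        coords=np.array(coords),
        labels=labels,
        ligand_coords=np.array(lig_coords) if lig_coords else np.empty((0, 3)),
        ligand_names=lig_names,
    )


def site_from_residue_list(structure: CAStructure, name: str, spec) -> Site:
    """Build a named site from explicit residue identifiers.

    Each entry of ``spec`` is ``(chain, resnum)`` or ``(chain, resnum,
    icode)``, or the string form ``"CHAIN:RESNUM[:ICODE]"``.  Duplicates
    are collapsed; unresolved entries raise with the offenders listed.
    """
    members: set[int] = set()
    bad: list[str] = []
    for entry in spec:
        if isinstance(entry, str):
            parts = entry.split(":")
            chain, resnum = parts[0], int(parts[1])
            icode = parts[2] if len(parts) > 2 else ""
        else:
            chain, resnum = entry[0], int(entry[1])
            icode = entry[2] if len(entry) > 2 else ""
        try:
            members.add(structure.index_of(chain, resnum, icode))
        except KeyError:
            bad.append(f"{chain}:{resnum}{':' + icode if icode else ''}")
    if bad:
        raise ValueError(f"site {name!r}: unresolved residues: {', '.join(bad)}")
    return Site(name=name, members=frozenset(members))


def site_from_ligand_contacts(
    structure: CAStructure,
    ligand_atoms: np.ndarray,
    cutoff: float = 8.0,
    name: str = "ligand_site",
) -> Site:
    """Residues whose Cα lies within ``cutoff`` Å of any ligand heavy atom.

    The default cutoff (8 Å) matches the outer edge of the attractive
    probe–protein well, so ligand-derived sites are commensurate with
    probe locations.
    """
    ligand_atoms = np.asarray(ligand_atoms, dtype=float).reshape(-1, 3)
    if len(ligand_atoms) == 0:
        raise ValueError("ligand_atoms is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    # (m, k) distance matrix; structures here are small enough for dense
    d = np.linalg.norm(
        structure.coords[:, None, :] - ligand_atoms[None, :, :], axis=-1
    )
    members = frozenset(np.nonzero((d <= cutoff).any(axis=1))[0].tolist())
    if not members:
        raise ValueError(
            f"no residue within {cutoff} Å of the ligand; try a larger cutoff"
        )
    return Site(name=name, members=members)


def _pdb_atom_line(
    serial: int,
    res_name: str,
    chain: str,
    resnum: int,
    icode: str,
    xyz: np.ndarray,
    occ: float,
    bfac: float,
) -> str:
    # PDB fixed-width ATOM record, Cα only
    return (
        f"ATOM  {serial:>5d}  CA  {res_name:<3s} {chain[:1]:1s}{resnum:>4d}"
        f"{(icode or ' '):1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{bfac:6.2f}           C  "
    )


def write_ca_pdb(structure: CAStructure, bfactors: np.ndarray | None = None) -> str:
    """Render the bead model as fixed-width PDB text (ATOM/TER/END)."""
    if bfactors is None:
        bfactors = np.zeros(structure.m)
    lines = []
    prev_chain = None
    serial = 0
    for i, (rid, label) in enumerate(zip(structure.residue_ids, structure.labels)):
        chain, resnum, icode = rid
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        lines.append(
            _pdb_atom_line(
                serial, label, chain, resnum, icode,
                structure.coords[i], 1.0, float(bfactors[i]),
            )
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_bfactor_pdb(structure: CAStructure, values: np.ndarray) -> str:
    """Write per-residue scalars into the B-factor column for surface coloring.

    Values are min–max scaled to [0, 100] and written with two decimals in
    the fixed-width B-factor column.  A constant field (zero range) maps to
    all 0.00, with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (structure.m,):
        raise ValueError(f"expected {structure.m} values, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    lo, hi = values.min(), values.max()
    if hi - lo == 0:
        log.warning("constant scalar field; all B-factors written as 0.00")
        scaled = np.zeros_like(values)
    else:
        scaled = 100.0 * (values - lo) / (hi - lo)
    return write_ca_pdb(structure, bfactors=scaled)


def read_bfactors(pdb_text: str) -> np.ndarray:
    """Read back the B-factor column of Cα ATOM records (for round-trips)."""
    vals = []
    for line in io.StringIO(pdb_text):
        if line.startswith("ATOM") and line[12:16].strip() == "CA":
            vals.append(float(line[60:66]))
    return np.array(vals)
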