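"""End-to-end pipeline: structure → modes → docking → λ → couplings.

A :class:`RunConfig` reifies one analysis run (one row of a simulation
parameter table).  All randomness flows from the single master seed, every
default is recorded into the emitted run manifest, and a rerun from the
same manifest is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .coupling import (
    CouplingMatrix,
    coupling_matrix,
    matrix_to_tsv,
    single_mode_coupling,
    site_residue_coupling,
)
from .docking import DockingParams, generate_probe_locations, locations_to_jsonl
from .enm import ENMParams, ModeSet, compute_enm_modes, modes_to_tsv
from .leverage import (
    LeverageMatrix,
    LeverageParams,
    leverage_to_tsv,
    profile_similarity,
    residue_leverage_matrix,
    score_locations,
    total_binding_leverage,
)
from .structure import (
    CAStructure,
    Site,
    read_ca_structure,
    site_from_residue_list,
    write_bfactor_pdb,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: input structure, stage parameters, sites, outputs."""

    pdb_path: str
    out_prefix: str
    seed: int = 0
    chains: list[str] | None = None
    exclude_ranges: list | None = None
    enm: ENMParams = field(default_factory=ENMParams)
    docking: DockingParams = field(default_factory=DockingParams)
    leverage: LeverageParams = field(default_factory=LeverageParams)
    sites: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, klass in (("enm", ENMParams), ("docking", DockingParams),
                           ("leverage", LeverageParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        cfg = cls(**d)
        cfg.docking.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    """Bundle of everything one pipeline run computes."""

    structure: CAStructure
    modes: ModeSet
    locations: list
    lam: LeverageMatrix
    sites: list[Site]
    couplings: CouplingMatrix | None
    site_residue: dict[str, np.ndarray]
    manifest: dict


def run_pipeline(
    config: RunConfig,
    structure: CAStructure | None = None,
    modes: ModeSet | None = None,
    write_files: bool = True,
) -> RunResult:
    """Execute all stages in order and (optionally) write the output files.

    ``structure``/``modes`` may be injected directly (e.g. designed modes
    for synthetic systems); otherwise they are read/computed from config.
    """
    t0 = time.time()
    stage = "read structure"
    try:
        if structure is None:
            structure = read_ca_structure(
                Path(config.pdb_path).read_text(),
                chains=config.chains,
                exclude_ranges=config.exclude_ranges,
            )
        log.info("structure: %d residues", structure.m)

        stage = "normal modes"
        if modes is None:
            modes = compute_enm_modes(structure, config.enm)
        log.info("modes: %d retained, %d trivial discarded",
                 modes.n, modes.trivial_count)

        stage = "docking"
        config.docking.seed = config.seed
        locations = generate_probe_locations(structure, config.docking)
        log.info("docking: %d bound locations of %d simulations",
                 len(locations), config.docking.n_sims)

        stage = "leverage"
        score_locations(structure, locations, modes, config.leverage)
        lam = residue_leverage_matrix(locations, structure.m, modes.n)

        stage = "coupling"
        sites = [
            site_from_residue_list(structure, name, spec)
            for name, spec in config.sites.items()
        ]
        couplings = coupling_matrix(lam, sites) if sites else None
        site_res = {
            s.name: site_residue_coupling(lam, s) for s in sites
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_residues": structure.m,
        "n_modes": modes.n,
        "trivial_modes": modes.trivial_count,
        "locations_generated": config.docking.n_sims,
        "locations_kept": len(locations),
        "runtime_s": round(time.time() - t0, 3),
    }
    result = RunResult(
        structure=structure,
        modes=modes,
        locations=locations,
        lam=lam,
        sites=sites,
        couplings=couplings,
        site_residue=site_res,
        manifest=manifest,
    )
    if write_files:
        _write_outputs(config, result)
    return result


def _write_outputs(config: RunConfig, res: RunResult) -> None:
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    p = str(prefix)
    Path(p + ".manifest.json").write_text(
        json.dumps(res.manifest, indent=2, sort_keys=True) + "\n"
    )
    Path(p + ".modes.tsv").write_text(modes_to_tsv(res.modes))
    Path(p + ".locations.jsonl").write_text(
        locations_to_jsonl(res.locations, res.structure, config.seed)
    )
    Path(p + ".lambda.tsv").write_text(leverage_to_tsv(res.lam, res.structure))
    sim = profile_similarity(res.lam)
    mode_names = [f"mode{mu}" for mu in res.lam.mode_ids]
    Path(p + ".profile_similarity.tsv").write_text(
        matrix_to_tsv(mode_names, sim.normalized)
    )
    total = total_binding_leverage(res.lam)
    Path(p + ".total_leverage.pdb").write_text(
        write_bfactor_pdb(res.structure, total)
    )
    if res.couplings is not None:
        Path(p + ".D.tsv").write_text(
            matrix_to_tsv(res.couplings.names, res.couplings.D)
        )
        Path(p + ".C.tsv").write_text(
            matrix_to_tsv(res.couplings.names, res.couplings.C)
        )
        Path(p + ".background.txt").write_text(f"{res.couplings.background:.10g}\n")
        for mu in res.lam.mode_ids:
            Dm = single_mode_coupling(res.lam, res.sites, mu)
            Path(p + f".D.mode{mu}.tsv").write_text(
                matrix_to_tsv(res.couplings.names, Dm)
            )
        for name, vec in res.site_residue.items():
            Path(p + f".DPi.{name}.tsv").write_text(
                "\n".join(
                    ":".join(str(x) for x in rid if x != "") + f"\t{v:.10g}"
                    for rid, v in zip(res.structure.residue_ids, vec)
                )
                + "\n"
            )
            Path(p + f".DPi.{name}.pdb").write_text(
                write_bfactor_pdb(res.structure, vec)
            )


def render_matrix_heatmaps(
    matrices: dict[str, tuple[list[str], np.ndarray, str]],
    out_prefix: str,
) -> list[str]:
    """Render coupling matrices as PNG heatmaps.

    ``matrices`` maps an output name to ``(site names, matrix, kind)`` with
    kind ``"D"`` (color scale 0 → measured max) or ``"C"`` (fixed 0 → 1).
    The color ramp runs cyan → magenta → white, low to high.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if not matrices:
        log.warning("no matrices to render")
        return []
    cmap = LinearSegmentedColormap.from_list(
        "leverage", ["cyan", "magenta", "white"]
    )
    written = []
    for name, (names, M, kind) in matrices.items():
        M = np.asarray(M, dtype=float)
        vmax = 1.0 if kind == "C" else max(float(M.max()), 1e-300)
        fig, ax = plt.subplots(figsize=(4 + 0.2 * len(names),) * 2)
        im = ax.imshow(M, cmap=cmap, vmin=0.0, vmax=vmax)
        ax.set_xticks(range(len(names)), names, rotation=90)
        ax.set_yticks(range(len(names)), names)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(name)
        out = f"{out_prefix}.{name}.png"
        fig.savefig(out, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(out)
    return written
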