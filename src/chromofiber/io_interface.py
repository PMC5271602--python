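"""Configuration, serialization, structure output and the command line.

The run configuration gathers every tunable model constant (stiffness
matrix, electrostatic scale and cutoff, steric and stacking parameters,
grids and seeds) and round-trips losslessly through YAML.  Fiber
structures are written as pseudo-atom PDB or XYZ traces (one pseudo-atom
per bp center, one chain per nucleosome+linker repeat unit).  The CLI is
a thin layer over the library: optimize | scan | topology | transition |
dlk-curve | nrl | synth.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field

import click
import numpy as np
import yaml

from .fiber_energy import (
    ElectrostaticsModel,
    EnergyModels,
    StackingModel,
    StericModel,
)
from .linker_mechanics import StiffnessModel
from .nucleosome_geometry import FiberParams, NucleosomeCore, make_ideal_core

__all__ = ["RunConfig", "run_cli", "cli", "write_structure", "read_xyz"]


@dataclass
class RunConfig:
    """All model constants and run settings, YAML round-trippable."""

    stiffness_matrix: list = field(
        default_factory=lambda: StiffnessModel().matrix.tolist()
    )
    electrostatic_scale: float = 0.5
    electrostatic_cutoff: float = 30.0
    stacking_e0: float = 8.0
    stacking_d0: float = 3.0
    stacking_sigma: float = 6.0
    steric_k_env: float = 2.0
    steric_k_dna: float = 0.5
    octamer_radius: float = 30.0
    seed: int = 0

    def to_models(self) -> EnergyModels:
        return EnergyModels(
            stiffness=StiffnessModel(np.array(self.stiffness_matrix)),
            electrostatics=ElectrostaticsModel(
                scale=self.electrostatic_scale, cutoff=self.electrostatic_cutoff
            ),
            steric=StericModel(
                k_env=self.steric_k_env,
                k_dna=self.steric_k_dna,
                octamer_radius=self.octamer_radius,
            ),
            stacking=StackingModel(
                e0=self.stacking_e0, d0=self.stacking_d0, sigma=self.stacking_sigma
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return RunConfig(**data)


# ---------------------------------------------------------------------------
# structure output
# ---------------------------------------------------------------------------


def write_structure(path, params: FiberParams, core: NucleosomeCore, linker, fmt: str = "pdb") -> None:
    """Write the fiber bp-center trace as pseudo-atom PDB or XYZ.

    One pseudo-atom (P) per bp center; PDB chains cycle per repeat unit.
    """
    from .dna_topology import FiberPath

    path_obj = FiberPath(params, core, linker)
    R, o = path_obj.bp_frames(params.N)
    fmt = fmt.lower()
    if fmt == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{o.shape[0]}\n")
            fh.write(f"chromofiber bp centers L={params.L} N={params.N}\n")
            for x, y, z in o:
                fh.write(f"P {x:12.3f} {y:12.3f} {z:12.3f}\n")
        return
    if fmt != "pdb":
        raise ValueError(f"unknown structure format: {fmt!r}")
    unit = core.n_bp + params.L
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    with open(path, "w") as fh:
        fh.write(f"REMARK   chromofiber trace L={params.L} N={params.N}\n")
        serial = 1
        for i, (x, y, z) in enumerate(o):
            chain = chains[(i // unit) % len(chains)]
            resseq = (i % unit) + 1
            fh.write(
                f"ATOM  {serial % 100000:5d}  P   DN {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P\n"
            )
            serial += 1
        fh.write("END\n")


def read_xyz(path) -> np.ndarray:
    """Read back an XYZ bp-center trace written by :func:`write_structure`."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        pts = [[float(v) for v in fh.readline().split()[1:4]] for _ in range(n)]
    return np.array(pts)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _parse_range(spec: str) -> list[float]:
    """'a:b' or 'a:b:step' inclusive ranges, or a single value."""
    parts = [float(p) for p in str(spec).split(":")]
    if len(parts) == 1:
        return parts
    lo, hi = parts[0], parts[1]
    step = parts[2] if len(parts) > 2 else 1.0
    return list(np.arange(lo, hi + 1e-9, step))


def _echo_provenance(**kwargs) -> None:
    from . import __version__

    click.echo(f"# chromofiber {__version__} :: " + json.dumps(kwargs, default=str), err=True)


@click.group()
def cli():
    """Mesoscopic two-start chromatin fiber modelling and DNA topology."""


@cli.command()
@click.option("--L", "L", type=int, required=True, help="linker length, bp")
@click.option("--rho", type=float, required=True, help="inclination angle, degrees")
@click.option("--out", type=click.Path(), default=None, help="JSON output path")
def optimize(L, rho, out):
    """Optimize fiber energy over (r, h, phi) at fixed L and rho."""
    from .fiber_optimizer import classify_topoisomer, optimize_fiber

    _echo_provenance(cmd="optimize", L=L, rho=rho)
    opt = optimize_fiber(L, rho)
    p = opt.params
    payload = {
        "L": L,
        "rho": rho,
        "r": p.r,
        "h": p.h,
        "phi": p.phi,
        "energy": opt.breakdown.as_dict(),
        "class": classify_topoisomer(p).label,
    }
    text = json.dumps(payload, indent=2)
    if out:
        with open(out, "w") as fh:
            fh.write(text)
    click.echo(text)


@cli.command()
@click.option("--L", "L_spec", required=True, help="linker range, e.g. 20:30:5")
@click.option("--rho", "rho_spec", required=True, help="rho range, e.g. -90:-20:10")
@click.option("--out", type=click.Path(), required=True, help="grid TSV path")
def scan(L_spec, rho_spec, out):
    """Scan the (rho, L) energy landscape; write a grid TSV."""
    from .fiber_optimizer import scan_landscape

    L_values = [int(v) for v in _parse_range(L_spec)]
    rho_values = _parse_range(rho_spec)
    _echo_provenance(cmd="scan", L=L_values, rho=rho_values)
    grid = scan_landscape(L_values, rho_values)
    grid.to_frame().to_csv(out, sep="\t", index=False)
    click.echo(f"wrote {len(L_values) * len(rho_values)} cells to {out}")


@cli.command()
@click.option("--L", "L", type=int, required=True)
@click.option("--N", "N", type=int, default=100, help="fiber size for topology")
@click.option("--rho", type=float, default=None, help="fix rho; default: optimal basin")
@click.option("--out", type=click.Path(), default=None)
def topology(L, N, rho, out):
    """Linking number of the optimal fiber: dTw, Wr, dLk, dLk per nucleosome."""
    from .dna_topology import FiberPath, linking_number
    from .fiber_optimizer import optimize_fiber, scan_optimal_series
    from .nucleosome_geometry import FiberParams

    _echo_provenance(cmd="topology", L=L, N=N, rho=rho)
    core = make_ideal_core()
    if rho is None:
        entry = scan_optimal_series([L], core=core, N_topology=N)[L]
        res_path = entry.path
        rho_used = entry.rho
    else:
        opt = optimize_fiber(L, rho)
        p = opt.params
        res_path = FiberPath(FiberParams(p.r, p.h, p.phi, rho, L, N), core, opt.linker)
        rho_used = rho
    res = linking_number(res_path, N)
    payload = {
        "N": N,
        "L": L,
        "rho": rho_used,
        "dTw": res.delta_tw,
        "Wr": res.wr,
        "dLk": res.delta_lk,
        "dLk_per_nuc": res.delta_lk_per_nucleosome,
    }
    text = json.dumps(payload, indent=2)
    if out:
        with open(out, "w") as fh:
            fh.write(text)
    click.echo(text)


@cli.command()
@click.option("--L", "L", type=int, required=True)
@click.option("--rho-min", type=float, default=-90.0)
@click.option("--rho-max", type=float, default=120.0)
@click.option("--step", type=float, default=5.0)
@click.option("--out", type=click.Path(), default=None)
def transition(L, rho_min, rho_max, step, out):
    """Scan dLk versus rho and locate the topoisomer transition."""
    from .fiber_optimizer import transition_scan

    _echo_provenance(cmd="transition", L=L)
    res = transition_scan(L, np.arange(rho_min, rho_max + 1e-9, step))
    payload = {
        "rho": res["rho"].tolist(),
        "dlk_per_nucleosome": res["dlk_per_nucleosome"].tolist(),
        "transition": res["transition"],
    }
    text = json.dumps(payload, indent=2)
    if out:
        with open(out, "w") as fh:
            fh.write(text)
    click.echo(text)


@cli.command("dlk-curve")
@click.option("--L", "L", type=int, required=True)
@click.option("--n-values", default="3:100:1", help="fiber sizes, range spec")
@click.option("--out", type=click.Path(), default=None)
def dlk_curve(L, n_values, out):
    """dLk per nucleosome as a function of fiber size N."""
    from .dna_topology import dlk_vs_N
    from .fiber_optimizer import scan_optimal_series

    _echo_provenance(cmd="dlk-curve", L=L)
    entry = scan_optimal_series([L])[L]
    Ns = [int(v) for v in _parse_range(n_values) if v >= 2]
    results = dlk_vs_N(entry.path, Ns)
    payload = {
        "L": L,
        "rho": entry.rho,
        "N": Ns,
        "dlk_per_nucleosome": [r.delta_lk_per_nucleosome for r in results],
    }
    text = json.dumps(payload, indent=2)
    if out:
        with open(out, "w") as fh:
            fh.write(text)
    click.echo(text)


@cli.command()
@click.option("--dyads", type=click.Path(exists=True), required=True, help="dyad BED")
@click.option("--groups", type=click.Path(exists=True), default=None, help="gene/rate/length TSV")
@click.option("--out", type=click.Path(), default=None)
def nrl(dyads, groups, out):
    """Estimate the nucleosome repeat length from a dyad map."""
    import pandas as pd

    from .nrl_pipeline import (
        DyadMap,
        GeneSet,
        call_peaks,
        estimate_nrl,
        occupancy_profile,
        select_gene_groups,
    )

    _echo_provenance(cmd="nrl", dyads=dyads)
    dm = DyadMap.from_bed(dyads)
    payload = {}
    if groups:
        gs = GeneSet(pd.read_csv(groups, sep="\t")).filter_min_length()
        up, down = select_gene_groups(gs)
        for name, grp in (("UP", up), ("DOWN", down)):
            pos, prof = occupancy_profile(dm, group=grp)
            est = estimate_nrl(call_peaks(pos, prof), n_genes=len(grp))
            payload[name] = est.as_dict()
    else:
        pos, prof = occupancy_profile(dm)
        est = estimate_nrl(call_peaks(pos, prof), n_genes=dm.n_genes)
        payload["all"] = est.as_dict()
    text = json.dumps(payload, indent=2)
    if out:
        with open(out, "w") as fh:
            fh.write(text)
    click.echo(text)


@cli.command()
@click.option("--nrl", "nrl_bp", type=float, default=165.0)
@click.option("--genes", type=int, default=860)
@click.option("--phase-sd", type=float, default=10.0)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), required=True, help="BED output path")
def synth(nrl_bp, genes, phase_sd, seed, out):
    """Generate a synthetic dyad map (BED)."""
    from .nrl_pipeline import synthesize_dyad_map

    _echo_provenance(cmd="synth", nrl=nrl_bp, genes=genes, seed=seed)
    dm = synthesize_dyad_map(n_genes=genes, nrl=nrl_bp, phase_sd=phase_sd, seed=seed)
    dm.to_bed(out)
    click.echo(f"wrote {len(dm.records)} dyad records to {out}")


def run_cli(argv=None) -> int:
    """Programmatic CLI entry point; returns the exit code."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code
    except SystemExit as exc:  # pragma: no cover
        return int(exc.code or 0)


if __name__ == "__main__":
    sys.exit(run_cli())
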