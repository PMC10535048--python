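"""Command-line workbench tying fixtures, solvers, and outputs together.

Commands
--------
gen-fixture   write contact, region, and basis-field CSVs for a fixture
optimize      single-objective multistart solve on one region
pareto        epsilon-constraint sweep over a primary + constrained region
baseline      random & bipolar reference statistics against the optimum
evaluate      objective of a user-supplied set of current fractions

Every stochastic command takes ``--seed`` and writes a JSON manifest
sufficient to re-run the command bit-identically.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import baseline_report
from .field_model import export_basis_fields, import_basis_fields, superpose
from .fixtures import get_fixture
from .multi_objective import (
    EpsilonSchedule,
    default_epsilon_schedule,
    pareto_sweep,
)
from .single_objective import (
    SolverSettings,
    multistart_solve,
    round_fractions,
)

logger = logging.getLogger(__name__)


def _write_manifest(out_dir: Path, command: str, payload: dict) -> None:
    manifest = {"tool": "steeropt", "version": __version__,
                "command": command, **payload}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _solution_frame(points, labels) -> pd.DataFrame:
    rows = []
    for idx, p in enumerate(points):
        rounded = round_fractions(p.alpha)
        row = {
            "label": f"sol{idx}",
            "classification": p.classification,
            "residual": p.residual_norm,
        }
        for name, val in p.objective.items():
            row[f"objective_{name}"] = val
        for lab, a in zip(labels, rounded.alpha):
            row[f"alpha_{lab}"] = a
        rows.append(row)
    return pd.DataFrame(rows)


def _settings_from(seed, n_starts) -> SolverSettings:
    return SolverSettings(seed=seed, n_starts=n_starts)


def _merge_config(config_path: Path | None, keys: dict,
                  defaults: dict | None = None) -> dict:
    """Resolve options: explicit flag > YAML config > default.

    The config may only contain keys the command understands; anything
    still unset after merging (and without a default) is an error.
    """
    cfg = {}
    if config_path is not None:
        cfg = yaml.safe_load(Path(config_path).read_text()) or {}
        if not isinstance(cfg, dict):
            raise click.UsageError("config must be a YAML mapping")
        unknown = set(cfg) - set(keys)
        if unknown:
            raise click.UsageError(f"unknown config keys: {sorted(unknown)}")
    defaults = defaults or {}
    merged = {
        k: v if v is not None else cfg.get(k, defaults.get(k))
        for k, v in keys.items()
    }
    missing = [k for k, v in merged.items() if v is None]
    if missing:
        raise click.UsageError(
            f"missing options {missing} (flags or --config)"
        )
    return merged


@click.group()
@click.version_option(__version__)
@click.option("-v", "--verbose", is_flag=True, help="Log solver statistics.")
def cli(verbose: bool) -> None:
    """Analytic current-steering optimization for multi-contact arrays."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command("gen-fixture")
@click.option("--fixture", required=True, type=str)
@click.option("--out", required=True, type=click.Path(path_type=Path))
def gen_fixture(fixture: str, out: Path) -> None:
    """Write contact table, region tables, and basis-field CSVs."""
    fx = get_fixture(fixture)
    out.mkdir(parents=True, exist_ok=True)
    contacts = pd.DataFrame(fx.contacts.positions, columns=["x", "y", "z"])
    contacts.insert(0, "label", list(fx.contacts.labels))
    contacts.to_csv(out / "contacts.csv", index=False)
    for name, region in fx.regions.items():
        basis = fx.basis(name)
        export_basis_fields(basis, out / f"basis_{name}.csv")
    _write_manifest(out, "gen-fixture", {"fixture": fixture})
    click.echo(f"wrote fixture {fixture!r} to {out}")


@cli.command()
@click.option("--config", type=click.Path(exists=True, path_type=Path),
              default=None, help="YAML mapping supplying unset options.")
@click.option("--fixture", type=str, default=None)
@click.option("--region", type=str, default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", required=True, type=click.Path(path_type=Path))
@click.option("--beta", type=float, default=None,
              help="Smooth-max scale; default auto (beta*field ~ 10).")
@click.option("--gamma", type=float, default=100.0)
@click.option("--n-starts", type=int, default=None)
def optimize(config, fixture, region, seed, out, beta, gamma,
             n_starts) -> None:
    """Single-objective solve: maximize the region's excitation field."""
    opts = _merge_config(config, {
        "fixture": fixture, "region": region, "seed": seed,
        "n_starts": n_starts,
    }, defaults={"n_starts": 200})
    fixture, region = opts["fixture"], opts["region"]
    seed, n_starts = int(opts["seed"]), int(opts["n_starts"])
    fx = get_fixture(fixture)
    basis = fx.basis(region)
    settings = _settings_from(seed, n_starts)
    params = None
    if beta is not None:
        from .smooth_ops import SmoothingParams
        params = SmoothingParams(beta=beta, gamma=gamma)
    points = multistart_solve(basis, params=params, settings=settings)
    out.mkdir(parents=True, exist_ok=True)
    df = _solution_frame(points, fx.contacts.labels)
    df.to_csv(out / "solutions.csv", index=False)
    _write_manifest(out, "optimize", {
        "fixture": fixture, "region": region, "seed": seed,
        "beta": beta, "gamma": gamma, "n_starts": n_starts,
        "n_solutions": len(points),
    })
    if not points:
        click.echo("warning: no converged solutions", err=True)
        return
    best = points[0]
    click.echo(f"{len(points)} critical points; "
               f"best objective {best.primary_objective:.6g} "
               f"({best.classification})")


@cli.command()
@click.option("--fixture", required=True, type=str)
@click.option("--roi", "roi", required=True, type=str)
@click.option("--roa", "roa", required=True, type=str)
@click.option("--seed", required=True, type=int)
@click.option("--out", required=True, type=click.Path(path_type=Path))
@click.option("--n-eps", type=int, default=25)
@click.option("--n-starts", type=int, default=60)
def pareto(fixture, roi, roa, seed, out, n_eps, n_starts) -> None:
    """Epsilon-constraint sweep: maximize ROI subject to a cap on the ROA."""
    fx = get_fixture(fixture)
    basis = fx.basis_for(roi, roa)
    settings = _settings_from(seed, n_starts)
    schedule = default_epsilon_schedule(
        roa, basis[roa], settings=settings, n_points=n_eps
    )
    front = pareto_sweep(roi, (roa,), schedule, basis, settings=settings)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in front.points:
        row = {"epsilon": p.epsilon[roa],
               "nondominated": p.nondominated}
        for name, val in p.objectives.items():
            row[f"objective_{name}"] = val
        rounded = round_fractions(p.config)
        for lab, a in zip(fx.contacts.labels, rounded.alpha):
            row[f"alpha_{lab}"] = a
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "pareto.csv", index=False)
    _write_manifest(out, "pareto", {
        "fixture": fixture, "roi": roi, "roa": roa, "seed": seed,
        "n_eps": n_eps, "n_starts": n_starts,
        "n_front_points": len(front.points),
    })
    click.echo(f"front with {len(front.points)} points "
               f"({len(front.nondominated)} nondominated)")


@cli.command()
@click.option("--fixture", required=True, type=str)
@click.option("--region", required=True, type=str)
@click.option("--seed", required=True, type=int)
@click.option("--out", required=True, type=click.Path(path_type=Path))
@click.option("--n-random", type=int, default=10_000)
@click.option("--n-starts", type=int, default=200)
def baseline(fixture, region, seed, out, n_random, n_starts) -> None:
    """Random and bipolar reference statistics against the optimum."""
    fx = get_fixture(fixture)
    basis = fx.basis(region)
    settings = _settings_from(seed, n_starts)
    points = multistart_solve(basis, settings=settings)
    maxima = [p for p in points if p.classification == "maximum"]
    if not maxima:
        click.echo("warning: optimizer found no maximum", err=True)
        sys.exit(0)
    optimum = maxima[0].primary_objective
    rng = np.random.default_rng(seed)
    report = baseline_report(basis, optimum, n_random=n_random, rng=rng)
    out.mkdir(parents=True, exist_ok=True)
    rows = [{"config": f"random{i}", "type": "random", "objective": o}
            for i, o in enumerate(report.random_objectives)]
    rows += [{"config": f"{c}->{a}", "type": "bipolar", "objective": o}
             for (c, a), o in zip(report.bipolar_pairs,
                                  report.bipolar_objectives)]
    pd.DataFrame(rows).to_csv(out / "baselines.csv", index=False)
    summary = {"optimum": optimum, "deficit": report.deficit,
               "best_bipolar": list(report.best_bipolar), **report.summary}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(out, "baseline", {
        "fixture": fixture, "region": region, "seed": seed,
        "n_random": n_random, "n_starts": n_starts,
    })
    click.echo(f"mean random deficit vs optimum: {report.deficit:.1%}")


@cli.command()
@click.option("--basis-csv", required=True,
              type=click.Path(exists=True, path_type=Path),
              help="Imported basis-field table (x,y,z then contact columns).")
@click.option("--alpha", required=True, type=str,
              help="Comma-separated current fractions, one per contact.")
@click.option("--direction", type=str, default="0,0,1")
def evaluate(basis_csv: Path, alpha: str, direction: str) -> None:
    """Exact max-field objective of a given configuration on imported fields."""
    from .field_model import FieldKind, RegionSpec

    r = np.array([float(x) for x in direction.split(",")])
    r = r / np.linalg.norm(r)
    meta = RegionSpec(name="imported", points=np.zeros((1, 3)), direction=r,
                      field_kind=FieldKind.ACTIVATING_FUNCTION)
    basis = import_basis_fields(basis_csv, meta)
    a = np.array([float(x) for x in alpha.split(",")])
    field = superpose(basis, a)
    click.echo(f"max field over {basis.m} points: {np.max(field):.10g}")


if __name__ == "__main__":
    cli()
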