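"""File formats: MID data CSV, flux/CI tables, trajectory export, manifests.

CSV dialect everywhere: comma separated, ``.`` decimal, mandatory header,
UTF-8.  The MID data file is wide-format with one row per (metabolite,
fragment, time): ``metabolite,fragment,time_s,m0..mK,sd0..sdK`` — unused
high-mass columns are left empty for small fragments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fitting import FitResult, MIDDataset, Observation
from .network import FluxMap
from .simulate import MIDTrajectory

__all__ = [
    "write_mid_csv",
    "read_mid_csv",
    "write_trajectory_csv",
    "write_flux_tsv",
    "read_flux_tsv",
    "write_fit_report",
    "write_ci_tsv",
    "write_manifest",
]


def _fragment_str(atoms: Iterable[int]) -> str:
    return ",".join(map(str, atoms))


def write_mid_csv(data: MIDDataset, path: str | Path) -> None:
    max_k = max(len(o.mid) for o in data.observations)
    rows = []
    for o in data.observations:
        row: dict = {
            "metabolite": o.metabolite,
            "fragment": _fragment_str(o.atoms),
            "time_s": o.time_s,
        }
        for k in range(max_k):
            row[f"m{k}"] = o.mid[k] if k < len(o.mid) else ""
            row[f"sd{k}"] = o.sd[k] if k < len(o.sd) else ""
        rows.append(row)
    cols = ["metabolite", "fragment", "time_s"]
    cols += [f"m{k}" for k in range(max_k)] + [f"sd{k}" for k in range(max_k)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_mid_csv(path: str | Path) -> MIDDataset:
    df = pd.read_csv(path)
    m_cols = sorted(
        (c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    obs = []
    for _, row in df.iterrows():
        atoms = tuple(int(a) for a in str(row["fragment"]).split(","))
        n = len(atoms) + 1
        mid = np.array([float(row[f"m{k}"]) for k in range(n)])
        sd = np.array([float(row[f"sd{k}"]) for k in range(n)])
        obs.append(Observation(str(row["metabolite"]), atoms, float(row["time_s"]), mid, sd))
    ds = MIDDataset(obs)
    ds.validate()
    return ds


def write_trajectory_csv(traj: MIDTrajectory, path: str | Path) -> None:
    """Long-format export: metabolite,fragment_atoms,time_s,mass_shift,fraction."""
    rows = []
    for emu in sorted(traj.mids):
        mids = traj.mids[emu]
        for ti, t in enumerate(traj.times):
            for k, frac in enumerate(mids[ti]):
                rows.append(
                    (emu.metabolite, _fragment_str(emu.atoms), float(t), k, float(frac))
                )
    pd.DataFrame(
        rows, columns=["metabolite", "fragment_atoms", "time_s", "mass_shift", "fraction"]
    ).to_csv(path, index=False)


def write_flux_tsv(fm: FluxMap, path: str | Path) -> None:
    rows = [
        {"reaction": r, "net": v, "exchange": fm.exchange.get(r, "")}
        for r, v in fm.net.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flux_tsv(path: str | Path) -> FluxMap:
    df = pd.read_csv(path, sep="\t")
    net = dict(zip(df["reaction"], df["net"].astype(float)))
    exch = {}
    if "exchange" in df:
        for r, x in zip(df["reaction"], df["exchange"]):
            if pd.notna(x) and str(x) != "":
                exch[str(r)] = float(x)
    return FluxMap(net, exch)


def write_fit_report(fit: FitResult, verdict: str, path: str | Path) -> None:
    report = {
        "ssr": fit.ssr,
        "dof": fit.dof,
        "verdict": verdict,
        "n_starts": fit.n_starts,
        "seed": fit.seed,
        "identifiable": fit.identifiable,
        "fluxes": fit.flux_map.net,
        "exchange_fluxes": fit.flux_map.exchange,
        "pool_sizes": fit.pool_sizes,
        "start_ssr": [s.ssr for s in fit.starts],
    }
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")


def write_ci_tsv(cis, path: str | Path) -> None:
    from .uncertainty import flux_point_estimate

    rows = [
        {
            "reaction": ci.reaction,
            "lower": ci.lower,
            "upper": ci.upper,
            "alpha": ci.alpha,
            "point_estimate": flux_point_estimate(ci),
        }
        for ci in cis
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profile_trace_csv(ci, path: str | Path) -> None:
    """Continuation trace of one profile-likelihood scan, for plotting."""
    pd.DataFrame(ci.trace or [], columns=["flux", "ssr"]).to_csv(path, index=False)


def read_biomass_yaml(path: str | Path):
    """Biomass composition from YAML: ``fractions:`` mapping plus optional
    ``monomer_tables:`` (umol monomer per g macromolecule)."""
    import yaml

    from .biomass import DEFAULT_MONOMER_TABLES, BiomassComposition

    raw = yaml.safe_load(Path(path).read_text())
    tables = {k: dict(v) for k, v in DEFAULT_MONOMER_TABLES.items()}
    for macro, table in (raw.get("monomer_tables") or {}).items():
        tables[macro] = {str(k): float(v) for k, v in table.items()}
    comp = BiomassComposition(
        {str(k): float(v) for k, v in raw["fractions"].items()}, tables
    )
    comp.validate()
    return comp


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Run manifest: config hash, seed and package version, enough to re-run
    deterministic stages bit-identically."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
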