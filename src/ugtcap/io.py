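"""CSV and parameter-file dialects shared by all pipeline stages.

Two CSV tables travel between stages:

* docking summaries — ``variant, ligand, S_DT, S_DH, udpga_correct_count``
* capacities — ``variant, genotype, Vc_percent_or_ND`` (the literal string
  ``ND`` encodes a not-detected capacity)

Fitted constants are stored as YAML so fits are diffable. Every file written
here starts with comment lines recording the tool version, the seed, and the
parameters that produced it, so outputs are traceable and reproducible;
readers skip ``#`` lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import UgtcapError
from .model import DockingSummary, ModelParams, Panel, VariantRecord

__all__ = [
    "header_lines",
    "write_csv",
    "read_csv",
    "write_summaries",
    "read_summaries",
    "write_capacities",
    "read_capacities",
    "write_params",
    "read_params",
    "build_panel",
    "panel_to_frames",
]

ND_TOKEN = "ND"


def header_lines(seed: int | None = None, **settings) -> list[str]:
    lines = [f"# ugtcap {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for key, value in settings.items():
        lines.append(f"# {key}={value}")
    return lines


def write_csv(
    path: str | Path,
    frame: pd.DataFrame,
    seed: int | None = None,
    **settings,
) -> None:
    """Write a DataFrame as CSV with a traceability header."""
    with open(path, "w") as fh:
        for line in header_lines(seed=seed, **settings):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_summaries(
    path: str | Path, summaries: list[DockingSummary], seed: int | None = None,
    **settings,
) -> None:
    frame = pd.DataFrame(
        [
            {
                "variant": s.variant,
                "ligand": s.ligand,
                "S_DT": s.S_DT,
                "S_DH": s.S_DH,
                "udpga_correct_count": s.udpga_correct_count,
            }
            for s in summaries
        ]
    )
    write_csv(path, frame, seed=seed, **settings)


def read_summaries(path: str | Path) -> list[DockingSummary]:
    frame = read_csv(path)
    required = {"variant", "ligand", "S_DT", "S_DH", "udpga_correct_count"}
    missing = required - set(frame.columns)
    if missing:
        raise UgtcapError(
            f"{path}: summary CSV missing columns {sorted(missing)}"
        )
    return [
        DockingSummary(
            variant=str(row.variant),
            ligand=str(row.ligand),
            S_DT=int(row.S_DT),
            S_DH=int(row.S_DH),
            udpga_correct_count=int(row.udpga_correct_count),
        )
        for row in frame.itertuples()
    ]


def write_capacities(
    path: str | Path, records: list[VariantRecord], seed: int | None = None,
    **settings,
) -> None:
    frame = pd.DataFrame(
        [
            {
                "variant": r.variant,
                "genotype": r.genotype,
                "Vc_percent_or_ND": ND_TOKEN if r.is_nd else r.v_c,
            }
            for r in records
        ]
    )
    write_csv(path, frame, seed=seed, **settings)


def read_capacities(path: str | Path) -> list[VariantRecord]:
    frame = read_csv(path)
    required = {"variant", "genotype", "Vc_percent_or_ND"}
    missing = required - set(frame.columns)
    if missing:
        raise UgtcapError(
            f"{path}: capacity CSV missing columns {sorted(missing)}"
        )
    records = []
    for row in frame.itertuples():
        raw = row.Vc_percent_or_ND
        if isinstance(raw, str) and raw.strip().upper() == ND_TOKEN:
            v_c = None
        elif pd.isna(raw):
            v_c = None
        else:
            v_c = float(raw)
        records.append(
            VariantRecord(variant=str(row.variant), genotype=str(row.genotype), v_c=v_c)
        )
    return records


def write_params(
    path: str | Path,
    params: ModelParams,
    ligand: str,
    sse: float | None = None,
    seed: int | None = None,
    **settings,
) -> None:
    """Write fitted constants as commented YAML."""
    payload = {
        "ligand": ligand,
        "sigma": float(params.sigma),
        "gamma": float(params.gamma),
        "mu": float(params.mu),
        "epsilon": float(params.epsilon),
        "beta": float(params.beta),
    }
    if sse is not None:
        payload["sse"] = float(sse)
    if seed is not None:
        payload["seed"] = int(seed)
    with open(path, "w") as fh:
        for line in header_lines(seed=seed, **settings):
            fh.write(line + "\n")
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_params(path: str | Path) -> tuple[ModelParams, Mapping]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise UgtcapError(f"{path}: not a parameter file")
    try:
        params = ModelParams(
            sigma=float(payload["sigma"]),
            gamma=float(payload["gamma"]),
            mu=float(payload["mu"]),
            epsilon=float(payload.get("epsilon", 0.0)),
            beta=float(payload["beta"]),
        )
    except KeyError as exc:
        raise UgtcapError(f"{path}: missing parameter {exc}") from exc
    return params, payload


def build_panel(
    summaries: list[DockingSummary],
    records: list[VariantRecord],
    ligand: str,
    wild_variant: str = "wild-type",
) -> Panel:
    """Assemble a Panel for one ligand from the two CSV tables.

    Any variant present in both tables becomes a member (including the
    wild type, which anchors the percent scale); the wild-type docking
    summary additionally defines beta.
    """
    summaries = [s for s in summaries if s.ligand == ligand]
    if not summaries:
        raise UgtcapError(f"no docking summaries for ligand {ligand!r}")
    by_variant = {s.variant: s for s in summaries}
    if wild_variant not in by_variant:
        raise UgtcapError(
            f"wild-type variant {wild_variant!r} absent from summaries"
        )
    record_by_variant = {r.variant: r for r in records}
    members = [
        (by_variant[v], record_by_variant[v])
        for v in by_variant
        if v in record_by_variant
    ]
    if not members:
        raise UgtcapError("no variant appears in both summaries and capacities")
    return Panel(
        ligand=ligand, wild_summary=by_variant[wild_variant], members=members
    )


def panel_to_frames(panel: Panel) -> tuple[pd.DataFrame, pd.DataFrame]:
    summaries = pd.DataFrame(
        [
            {
                "variant": s.variant,
                "ligand": s.ligand,
                "S_DT": s.S_DT,
                "S_DH": s.S_DH,
                "udpga_correct_count": s.udpga_correct_count,
            }
            for s, _ in panel.members
        ]
    )
    capacities = pd.DataFrame(
        [
            {
                "variant": r.variant,
                "genotype": r.genotype,
                "Vc_percent_or_ND": ND_TOKEN if r.is_nd else r.v_c,
            }
            for _, r in panel.members
        ]
    )
    return summaries, capacities
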