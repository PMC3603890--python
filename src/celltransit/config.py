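"""YAML/JSON run-configuration loading and saving."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .geometry import AxisymChannel, RectChannel
from .leakage import Plasma
from .rheology import CellModel
from .scenarios import RunConfig

__all__ = ["load_config", "dump_config", "config_to_dict", "config_from_dict"]

_CHANNEL_TYPES = {"rect": RectChannel, "axisym": AxisymChannel}


def config_to_dict(cfg: RunConfig) -> dict:
    ch = cfg.channel
    channel = {"type": "axisym" if isinstance(ch, AxisymChannel) else "rect"}
    if isinstance(ch, AxisymChannel):
        channel.update(
            L=ch.L, r_pipe=ch.r_pipe, r_con=ch.r_con, r_min=ch.r_min,
            delta=ch.delta,
        )
    else:
        channel.update(
            W=ch.W, L=ch.L, H=ch.H, R_con=ch.R_con, W_con=ch.W_con,
            delta=ch.delta, H_inlet=ch.H_inlet,
        )
    return {
        "config_id": cfg.config_id,
        "channel": channel,
        "cell": {
            "mu_cell_Pa_s": cfg.cell.mu_cell,
            "G_cell_Pa": cfg.cell.G_cell,
            "cortical_tension_pN_per_um": cfg.cell.T_c,
            "R_cell_um": cfg.cell.R_cell,
            "poisson": cfg.cell.nu,
            "membrane_E_Pa": cfg.cell.E_mem,
            "membrane_thickness_nm": cfg.cell.h_mem,
        },
        "plasma": {"viscosity_Pa_s": cfg.plasma.mu_p,
                   "density_kg_m3": cfg.plasma.rho_p},
        "drive": {"dP_total_Pa": cfg.dP_total, "dt_s": cfg.dt},
    }


def config_from_dict(d: dict) -> RunConfig:
    ch_d = dict(d.get("channel", {}))
    ch_type = ch_d.pop("type", "rect")
    if ch_type not in _CHANNEL_TYPES:
        raise ValueError(f"unknown channel type {ch_type!r}")
    channel = _CHANNEL_TYPES[ch_type](**ch_d)
    cell_d = d.get("cell", {})
    cell = CellModel(
        mu_cell=cell_d.get("mu_cell_Pa_s", 31.0),
        G_cell=cell_d.get("G_cell_Pa", 186.0),
        T_c=cell_d.get("cortical_tension_pN_per_um", 31.0),
        R_cell=cell_d.get("R_cell_um", 4.0),
        nu=cell_d.get("poisson", 0.4999),
        E_mem=cell_d.get("membrane_E_Pa", 1e-4),
        h_mem=cell_d.get("membrane_thickness_nm", 1.0),
    )
    pl_d = d.get("plasma", {})
    plasma = Plasma(
        mu_p=pl_d.get("viscosity_Pa_s", 1.2e-3),
        rho_p=pl_d.get("density_kg_m3", 1.03e3),
    )
    drive = d.get("drive", {})
    return RunConfig(
        config_id=d.get("config_id", "run"),
        channel=channel,
        cell=cell,
        plasma=plasma,
        dP_total=drive.get("dP_total_Pa", 40.0),
        dt=drive.get("dt_s", 1e-3),
        provenance=d.get("provenance", "user"),
    )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
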