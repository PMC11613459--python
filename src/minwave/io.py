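"""Reading and writing the package's tabular interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import DiffusionCoefficients, KineticParameters
from .simulator import Kymograph

__all__ = [
    "read_parameter_sets",
    "write_parameter_sets",
    "kymograph_to_frame",
    "write_kymograph",
    "read_config",
]

_PARAM_COLUMNS = ["set_id", "k_D", "k_dD", "k_dE", "k_de", "k_ADP_ATP", "D_D", "D_E", "D_d", "D_de"]


def read_parameter_sets(path: str | Path) -> pd.DataFrame:
    """Parameter-set CSV with columns set_id, k_D, ..., D_de."""
    df = pd.read_csv(path)
    missing = set(_PARAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter CSV is missing columns: {sorted(missing)}")
    return df


def write_parameter_sets(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _PARAM_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols or None)


def params_from_row(row: pd.Series) -> tuple[KineticParameters, DiffusionCoefficients]:
    params = KineticParameters(
        k_D=row["k_D"], k_dD=row["k_dD"], k_dE=row["k_dE"],
        k_de=row["k_de"], k_ADP_ATP=row["k_ADP_ATP"],
    )
    D = DiffusionCoefficients(D_D=row["D_D"], D_E=row["D_E"], D_d=row["D_d"], D_de=row["D_de"])
    return params, D


def kymograph_to_frame(kymo: Kymograph) -> pd.DataFrame:
    """Long-format table (time_s, position_um, species, density)."""
    rows = []
    if kymo.raw is not None:
        from .model_core import SPECIES

        for s_ix, name in enumerate(SPECIES):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": np.repeat(kymo.times, kymo.positions.size),
                        "position_um": np.tile(kymo.positions, kymo.times.size),
                        "species": name,
                        "density": kymo.raw[:, s_ix, :].ravel(),
                    }
                )
            )
    rows.append(
        pd.DataFrame(
            {
                "time_s": np.repeat(kymo.times, kymo.positions.size),
                "position_um": np.tile(kymo.positions, kymo.times.size),
                "species": "membrane_intensity",
                "density": kymo.intensity.ravel(),
            }
        )
    )
    return pd.concat(rows, ignore_index=True)


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    kymograph_to_frame(kymo).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    """Simulation/synthesis config from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
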