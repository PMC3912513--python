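"""Tabular text output: spectra/fixed points as CSV + JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import NetworkConfig, dump_config

__all__ = ["write_csv_with_sidecar", "spectrum_table", "fixed_point_table"]


def write_csv_with_sidecar(path, frame: pd.DataFrame, config: NetworkConfig,
                           extra: dict | None = None) -> None:
    """Write a CSV with a fixed numeric format and a .json sidecar that
    echoes the configuration and code version (reproducibility)."""
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.12e")
    meta = {"config": dump_config(config), "version": __version__,
            "columns": list(frame.columns)}
    if extra:
        meta.update(extra)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def spectrum_table(result) -> pd.DataFrame:
    return pd.DataFrame({
        "k": result.k_index,
        "phi_k": result.wavenumbers,
        "lambda_k": result.lam,
        "omega_k": result.omega,
        "abs_mu_k": np.abs(result.multipliers),
    })


def fixed_point_table(fp) -> pd.DataFrame:
    N = fp.config.N
    return pd.DataFrame({
        "j": np.arange(1, N),
        "X_j": fp.potentials_X,
    })
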