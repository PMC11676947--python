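"""Deterministic fixture generation and packaged reference data access."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import sha256_of, write_coefficients, write_manifest, write_raster, write_table
from .network import build_connectivity, simulate_network
from .params import cell_preset, network_defaults
from .stimuli import OUNoiseSpec, sample_ou
from .transfer import (COEFF_NAMES, InputConnectivity, TFCoefficients,
                       default_rate_grid, fit_transfer_function,
                       sample_single_cell_rates)

__all__ = ["load_spindle_coefficients", "make_fixtures", "refit_spindle_tf"]

SPINDLE_FIT_SETTINGS = dict(duration=5000.0, reps=10, seed=7)


def load_spindle_coefficients() -> tuple[TFCoefficients, TFCoefficients]:
    """The packaged spindle-state transfer-function refit (TC, RE).

    Produced by this package's own fitting pipeline with the spindle
    V_reset overrides (see the data file header); regenerate with
    ``thalmf make-fixtures``.
    """
    with resources.files("thalmf.data").joinpath("spindle_tf.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    out = []
    for cell in ("TC", "RE"):
        row = df[df["cell"] == cell].iloc[0]
        out.append(TFCoefficients(P=row[list(COEFF_NAMES)].to_numpy(dtype=float),
                                  cell=cell))
    return tuple(out)


def refit_spindle_tf(reps: int | None = None, seed: int | None = None):
    """Re-run the two-stage fit for both spindle presets; returns results."""
    settings = dict(SPINDLE_FIT_SETTINGS)
    if reps is not None:
        settings["reps"] = reps
    if seed is not None:
        settings["seed"] = seed
    out = {}
    for cell, K_i in (("TC", 25.0), ("RE", 150.0)):
        p = cell_preset(f"{cell}_spindle")
        ic = InputConnectivity(K_e=25.0, K_i=K_i, params=p)
        tab = sample_single_cell_rates(p, ic, default_rate_grid(),
                                       duration=settings["duration"],
                                       reps=settings["reps"], seed=settings["seed"])
        out[cell] = fit_transfer_function(tab, p, ic)
    return out


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Small deterministic fixture set with a checksum manifest.

    - a 2 s awake network raster (two-column text + sidecar metadata)
    - a coarse single-cell rate grid suitable for fit testing
    - an OU conductance path
    - the reference effective-threshold amplitudes (both cell types)
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    files = []

    net = network_defaults(state="awake", seed=seed)
    conn = build_connectivity(net)
    raster, _ = simulate_network(conn, net, P_drive=4.0, S_drive=0.0,
                                 duration=2000.0, seed=int(rng.integers(2**31)))
    raster_path = out / "awake_raster.tsv"
    write_raster(raster_path, raster, {"P_Hz": 4.0, "state": "awake", "seed": seed})
    files.append(raster_path)

    p = cell_preset("TC_awake")
    ic = InputConnectivity(K_e=25.0, K_i=25.0, params=p)
    grid = default_rate_grid(n_e=10, nu_i_values=(0.0, 10.0, 20.0, 40.0))
    tab = sample_single_cell_rates(p, ic, grid, duration=1000.0, reps=3,
                                   seed=int(rng.integers(2**31)))
    grid_path = out / "tc_rate_grid.tsv"
    write_table(grid_path, tab, {"cell": "TC_awake", "K_e": 25, "K_i": 25,
                                 "duration_ms": 1000, "reps": 3})
    files.append(grid_path)

    ou = sample_ou(OUNoiseSpec(mean=5.0, sd=5.0, tau_corr=20.0,
                               target="conductance_e"),
                   duration=2000.0, dt=0.5, seed=int(rng.integers(2**31)))
    ou_path = out / "ou_path.tsv"
    write_table(ou_path, pd.DataFrame({"t_ms": np.arange(ou.size) * 0.5, "g_nS": ou}),
                {"mean_nS": 5.0, "sd_nS": 5.0, "tau_ms": 20.0})
    files.append(ou_path)

    for cell in ("TC", "RE"):
        cpath = out / f"reference_tf_{cell}.tsv"
        write_coefficients(cpath, TFCoefficients.reference(cell),
                           {"source": "reference awake fit"})
        files.append(cpath)

    manifest = write_manifest(out / "manifest.json",
                              {"command": "make-fixtures", "out_dir": str(out)},
                              files, seed=seed)
    return {"files": [str(f) for f in files],
            "checksums": {str(f): sha256_of(f) for f in files},
            "manifest": manifest}
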