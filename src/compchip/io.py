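"""Tab-delimited I/O with reproducibility headers.

Every table the pipeline writes carries ``#`` comment lines recording the
tool version, a hash of the effective configuration, and the seed, so a run
can be identified from any of its artifacts.  Coordinates are 0-based
half-open (BED convention); times are minutes; all tables are UTF-8 TSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .induction import InductionCurve
from .kinetics import BiasTable

__all__ = [
    "PipelineConfig",
    "config_hash",
    "provenance_header",
    "write_table",
    "read_table",
    "read_bed",
    "write_bias_table",
    "read_bias_table",
]


def config_hash(params: dict) -> str:
    """Stable short hash of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(params: dict, seed: int | None = None) -> str:
    lines = [f"compchip {__version__}", f"config_hash={config_hash(params)}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    return "\n".join(lines)


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None,
                seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if params is not None:
            for line in provenance_header(params, seed).splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED4 file into chrom/start/end[/name] columns."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise ValueError("BED file needs at least 3 columns")
    cols = ["chrom", "start", "end"] + (["name"] if df.shape[1] >= 4 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    return df


def write_bias_table(table: BiasTable, path: str | Path) -> None:
    """Persist a bias lookup table with its generating parameters in the header."""
    meta = {
        "rho_inf": table.induction.rho_inf,
        "t_ind": table.induction.t_ind,
        "hill_n": table.induction.hill_n,
        "k_a": table.k_a,
        "times": list(table.times),
    }
    with open(path, "w") as fh:
        fh.write(f"# compchip {__version__} bias table\n")
        fh.write(f"# meta={json.dumps(meta, sort_keys=True)}\n")
        pd.DataFrame({"k_d_true": table.k_d_true, "k_d_ideal": table.k_d_ideal}).to_csv(
            fh, sep="\t", index=False, float_format="%.12g")


def read_bias_table(path: str | Path) -> BiasTable:
    meta = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta="):
                meta = json.loads(line[len("# meta="):])
            if not line.startswith("#"):
                break
    if meta is None:
        raise ValueError(f"{path}: missing bias-table metadata header")
    df = read_table(path)
    induction = InductionCurve(meta["rho_inf"], meta["t_ind"], meta["hill_n"])
    return BiasTable(k_d_true=df["k_d_true"].to_numpy(),
                     k_d_ideal=df["k_d_ideal"].to_numpy(),
                     k_a=meta["k_a"], times=np.asarray(meta["times"]),
                     induction=induction)


@dataclass
class PipelineConfig:
    """Knobs for the end-to-end pipeline, loadable from a YAML mapping."""

    seed: int = 0
    hill_n: int = 4
    fdr: float = 0.05
    t0_min: float = 24.5
    max_relative_rss: float = 0.003
    max_pct_err: float = 50.0
    k_a: float = 0.01
    n_perm: int = 10000
    rho_inf: float | None = None  # None: fit from the induction table
    t_ind: float | None = None
    n_loci: int = 200
    noise_sigma_log2: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"schema: {sorted(known)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
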