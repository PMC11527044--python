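"""Dataset and result I/O for the command-line workflow.

CSV in, JSON out.  Every result artifact echoes the configuration and seed
that produced it, so a run is reproducible from its own output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dgp import CausalDataset

__all__ = ["read_dataset", "write_dataset", "write_result", "read_result"]

__version__ = "0.1.0"


@dataclass
class ColumnRoles:
    outcome: str
    treatment: str | None = None
    covariates: list[str] | None = None


def read_dataset(path, outcome: str = "Y", treatment: str | None = "A",
                 covariates: list[str] | None = None,
                 treatment_map: dict | None = None) -> CausalDataset:
    """Read a delimited-text dataset into a validated CausalDataset.

    ``covariates=None`` uses every column other than outcome and treatment.
    Non-numeric treatment labels are coerced to {0, 1} via ``treatment_map``
    (e.g. ``{"ctrl": 0, "trt": 1}``).  Missing values are an error listing
    the offending rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = [outcome] + ([treatment] if treatment else [])
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in needed]
    else:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns missing: {missing}")
    use = df[covariates + needed]
    if use.isna().any().any():
        bad = use.index[use.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in rows {bad[:20]}"
                         + (" ..." if len(bad) > 20 else ""))
    a = df[treatment]
    if treatment_map is not None:
        a = a.map(treatment_map)
        if a.isna().any():
            raise ValueError("treatment values not covered by the mapping")
    a = a.astype(float).to_numpy()
    if not np.all(np.isin(a, (0.0, 1.0))):
        raise ValueError("treatment column must be binary 0/1 "
                         "(use treatment_map for labelled arms)")
    return CausalDataset(W=df[covariates].to_numpy(dtype=float), A=a,
                         Y=df[outcome].to_numpy(dtype=float))


def write_dataset(data: CausalDataset, path) -> None:
    """Write a causal dataset as CSV with header W1..Wd, A, Y."""
    cols = {f"W{i+1}": data.W[:, i] for i in range(data.d)}
    cols["A"] = data.A
    cols["Y"] = data.Y
    # 17 significant digits make the text round-trip bit-exact
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_result(result, path, config: dict | None = None,
                 seed: int | None = None) -> None:
    """Serialize a result object to JSON with config echo and version."""
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    out = {"result": payload, "config": config or {}, "seed": seed,
           "version": __version__}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


def read_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
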