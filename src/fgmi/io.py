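"""CSV / JSON serialization for datasets and imputation stacks."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .smc import ImputationStack

__all__ = ["read_data", "write_data", "write_stack", "read_stack"]


def read_data(
    path: str | Path,
    time_col: str = "time",
    status_col: str = "status",
) -> pd.DataFrame:
    """Read a subject-level competing-risks table; missing cells become NaN."""
    df = pd.read_csv(path)
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} not found in {path}")
    return df


def write_data(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, index=False)


def write_stack(stack: ImputationStack, directory: str | Path, prefix: str = "imp") -> None:
    """Write a stack as numbered CSVs plus a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, df in enumerate(stack.datasets, start=1):
        df.to_csv(directory / f"{prefix}_{i:03d}.csv", index=False)
    manifest = {"m": len(stack.datasets), "prefix": prefix, **stack.meta}
    (directory / "manifest.json").write_text(json.dumps(manifest, default=str, indent=2))


def read_stack(directory: str | Path) -> ImputationStack:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    prefix = manifest.get("prefix", "imp")
    datasets = [
        pd.read_csv(directory / f"{prefix}_{i:03d}.csv")
        for i in range(1, manifest["m"] + 1)
    ]
    return ImputationStack(datasets, manifest)
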