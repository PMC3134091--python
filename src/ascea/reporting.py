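"""Tabular writers and run manifests.

Output tables are plain delimited text with one header row; NOK amounts are
rounded to whole kroner and QALY-scale quantities to two decimals, matching
the precision the published tables use.  Every run directory receives
exactly one JSON manifest recording the command, seed, iteration count,
input files with content hashes, package version and timestamp.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_table", "write_manifest", "verify_manifest", "file_hash"]

_NOK_PREFIXES = ("cost", "delta_cost", "icer", "nmb")


def _round_for_print(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind not in "fc":
            continue
        if any(str(col).startswith(p) for p in _NOK_PREFIXES):
            out[col] = out[col].round(0)
        elif str(col).startswith(("qaly", "delta_qaly", "life_years",
                                  "probability")):
            out[col] = out[col].round(4 if str(col).startswith("prob")
                                      else 2)
    return out


def write_table(result, layout: str, path) -> Path:
    """Write a result object as a delimited table.

    ``layout`` is one of:

    * ``arm`` -- per-arm, per-horizon effects and cost components (the
      Table-4-style view); expects a :class:`~ascea.psa.PsaOutput`;
    * ``incremental`` -- reference-vs-comparator increments with ICER or
      dominance flag (Table-5-style); expects a PsaOutput;
    * ``ceac`` -- long-format acceptability curve (wtp, arm, probability);
      expects a PsaOutput or a :class:`~ascea.outcomes.CEResult`;
    * ``frame`` -- any DataFrame as-is.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if layout == "arm":
        df = result.arm_table()
    elif layout == "incremental":
        df = result.incremental_table()
        df["icer_or_dominance"] = [
            d if d else (f"{i:.0f}" if np.isfinite(i) else "undefined")
            for i, d in zip(df["icer"], df["dominance"])]
    elif layout == "ceac":
        ce = result.ce[max(result.ce)] if hasattr(result, "ce") else result
        df = ce.ceac
    elif layout == "frame":
        df = result
    else:
        raise ValueError(f"unknown layout {layout!r}")
    _round_for_print(df).to_csv(path, index=False)
    return path


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, seed, iterations,
                   inputs: dict[str, str], extra: dict | None = None
                   ) -> Path:
    """Write the single run manifest for an output directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "iterations": iterations,
        "inputs": {name: {"path": str(p), "sha256": file_hash(p)}
                   for name, p in inputs.items()},
        "version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def verify_manifest(path) -> bool:
    """Re-hash the manifest's inputs; True iff all hashes still match."""
    manifest = json.loads(Path(path).read_text())
    return all(file_hash(rec["path"]) == rec["sha256"]
               for rec in manifest["inputs"].values())
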