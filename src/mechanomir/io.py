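"""File-format plumbing: TSV tables with provenance headers, TIFF image pairs.

Every table this package writes starts with a comment header recording the
tool version, the seed, and a configuration hash, so any output file can be
traced back to the run that produced it.  Readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import tifffile

from .synthetic import SyntheticWoundPair

__all__ = [
    "config_hash",
    "write_tsv",
    "read_tsv",
    "write_wound_pair",
    "read_image",
    "write_pathway_exports",
    "read_pathway_exports",
]

_VERSION = "0.1.0"

AREA_COLUMNS = ["condition", "replicate_id", "area_initial", "area_final"]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(seed: int | None, cfg_hash: str | None) -> str:
    parts = [f"mechanomir v{_VERSION}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return "# " + " | ".join(parts) + "\n"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index: bool = False,
) -> Path:
    """Write a TSV with a provenance header; floats at fixed precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by this package (or any headerless TSV)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_wound_pair(
    pair: SyntheticWoundPair,
    prefix: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> dict[str, Path]:
    """Write a wound pair as two 16-bit TIFFs plus a truth-area sidecar TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "initial": prefix.with_name(prefix.name + "_initial.tif"),
        "final": prefix.with_name(prefix.name + "_final.tif"),
        "truth": prefix.with_name(prefix.name + "_truth.tsv"),
    }
    tifffile.imwrite(paths["initial"], pair.image_initial)
    tifffile.imwrite(paths["final"], pair.image_final)
    truth = pd.DataFrame(
        {
            "true_area_initial_px2": [pair.true_area_initial],
            "true_area_final_px2": [pair.true_area_final],
            "pixel_size_um": [pair.pixel_size],
        }
    )
    write_tsv(truth, paths["truth"], seed=seed, cfg_hash=cfg_hash)
    return paths


def read_image(path: str | Path):
    return tifffile.imread(path)


def write_pathway_exports(
    exports: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> Path:
    """Serialise a long-format export table; target sets semicolon-joined."""
    df = exports.copy()
    df["targets"] = df["targets"].map(
        lambda t: ";".join(sorted(t)) if not isinstance(t, str) else t
    )
    return write_tsv(df, path, seed=seed, cfg_hash=cfg_hash)


def read_pathway_exports(path: str | Path) -> pd.DataFrame:
    """Read an export table, restoring target sets from joined strings."""
    df = read_tsv(path)
    df["targets"] = df["targets"].map(
        lambda s: frozenset(t for t in str(s).split(";") if t)
    )
    return df
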