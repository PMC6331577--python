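"""Plain-text interchange: tab-separated tables with provenance headers.

Every artefact written by the pipeline starts with ``#``-prefixed header
lines recording the package version, the top-level seed and a hash of the
run configuration, so any table can be traced to the run that produced it.
Genotype matrices are written individuals x loci with 0/1/2 calls and
``NA`` for missing; mitochondrial haplotypes use the same layout with 0/1
alleles.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .ancestry import ReferencePanel

__all__ = [
    "write_table",
    "read_table",
    "write_genotypes",
    "read_genotypes",
    "write_panel",
    "read_panel",
    "config_hash",
]


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(seed: Optional[int], extra: Optional[dict]) -> list[str]:
    from . import __version__

    meta = {"package": f"introgress-stock {__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if extra:
        meta.update(extra)
    return [f"# {k}: {v}" for k, v in meta.items()]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    extra_header: Optional[dict] = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(seed, extra_header):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], index_col=index_col)


def write_genotypes(
    matrix: pd.DataFrame, path: str | Path, seed: Optional[int] = None,
    extra_header: Optional[dict] = None,
) -> None:
    """Write an individuals x loci call matrix (integer calls, NA missing)."""
    out = matrix.copy()
    out.index.name = "individual_id"
    formatted = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(seed, extra_header):
            fh.write(line + "\n")
        formatted.to_csv(fh, sep="\t")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], index_col="individual_id")
    return df.astype(float)


_PANEL_COLS = ["locus_id", "wild_freq", "farmed_freq", "diagnostic", "mt"]


def write_panel(panel: ReferencePanel, path: str | Path, seed: Optional[int] = None) -> None:
    """Panel as a locus table; the header names the scaling constants."""
    nuclear = pd.DataFrame(
        {
            "locus_id": list(panel.locus_ids),
            "wild_freq": panel.wild_freq,
            "farmed_freq": panel.farmed_freq,
            "diagnostic": panel.diagnostic.astype(int),
            "mt": 0,
        }
    )
    mt = pd.DataFrame(
        {
            "locus_id": list(panel.mt_locus_ids),
            "wild_freq": panel.mt_wild_freq,
            "farmed_freq": panel.mt_farmed_freq,
            "diagnostic": 0,
            "mt": 1,
        }
    )
    write_table(
        pd.concat([nuclear, mt], ignore_index=True),
        path,
        seed=seed,
        extra_header={"P_W": repr(panel.p_w), "P_D": repr(panel.p_d)},
    )


def read_panel(path: str | Path) -> ReferencePanel:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    df = read_table(path)
    missing = [c for c in _PANEL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"panel table lacks columns {missing}")
    nuc = df[df["mt"] == 0]
    mt = df[df["mt"] == 1]
    return ReferencePanel(
        locus_ids=tuple(nuc["locus_id"]),
        wild_freq=nuc["wild_freq"].to_numpy(),
        farmed_freq=nuc["farmed_freq"].to_numpy(),
        diagnostic=nuc["diagnostic"].to_numpy().astype(bool),
        mt_locus_ids=tuple(mt["locus_id"]),
        mt_wild_freq=mt["wild_freq"].to_numpy(),
        mt_farmed_freq=mt["farmed_freq"].to_numpy(),
        p_w=float(meta.get("P_W", 0.0644)),
        p_d=float(meta.get("P_D", 0.903)),
    )
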