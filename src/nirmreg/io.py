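"""Readers, writers and run manifests.

All tabular artifacts are header-bearing TSVs; the draws archive is a
compressed NumPy ``.npz`` with an embedded JSON schema block, readable
back into :class:`~nirmreg.sampler.PosteriorSamples` without loss.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distances import DistanceDataset
from .sampler import PosteriorSamples

ARCHIVE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# sequences and trees
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> dict[str, str]:
    """FASTA -> {sequence id: sequence string} (ids must match tree labels)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_alignment(sequences: dict[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq("".join(seq)), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Rooted Newick tree with labeled internal nodes."""
    return dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True
    )


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# distance tables
# ---------------------------------------------------------------------------

def write_distances(dataset: DistanceDataset, path: str | Path) -> None:
    """Long-format TSV: site, property, y, x, y_star, x_star, n_obs."""
    rows = []
    has_raw = dataset.y is not None and dataset.x is not None
    for i, site in enumerate(dataset.sites):
        for j, prop in enumerate(dataset.properties):
            rows.append({
                "site": site,
                "property": prop,
                "y": dataset.y[i, j] if has_raw else np.nan,
                "x": dataset.x[i, j] if has_raw else np.nan,
                "y_star": dataset.y_star[i, j],
                "x_star": dataset.x_star[i, j],
                "n_obs": dataset.n_obs[i],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_distances(path: str | Path, bounded: bool = True) -> DistanceDataset:
    """Read a distances TSV back into a dataset (bypassing sequence input)."""
    df = pd.read_csv(path, sep="\t")
    required = {"site", "property", "y_star", "x_star", "n_obs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"distances table missing columns: {sorted(missing)}")
    sites = tuple(dict.fromkeys(df["site"].tolist()))
    props = tuple(dict.fromkeys(df["property"].tolist()))
    pivot_y = df.pivot(index="site", columns="property", values="y_star")
    pivot_x = df.pivot(index="site", columns="property", values="x_star")
    y_star = pivot_y.loc[list(sites), list(props)].to_numpy(dtype=float)
    x_star = pivot_x.loc[list(sites), list(props)].to_numpy(dtype=float)
    n_obs = (
        df.drop_duplicates("site").set_index("site").loc[list(sites), "n_obs"]
        .to_numpy(dtype=int)
    )
    has_raw = "y" in df.columns and df["y"].notna().all()
    kwargs = {}
    if has_raw:
        kwargs["y"] = df.pivot(index="site", columns="property", values="y") \
            .loc[list(sites), list(props)].to_numpy(dtype=float)
        kwargs["x"] = df.pivot(index="site", columns="property", values="x") \
            .loc[list(sites), list(props)].to_numpy(dtype=float)
    return DistanceDataset(
        sites=sites, properties=props, y_star=y_star, x_star=x_star,
        n_obs=n_obs, zero_mask=(y_star == 0.0), bounded=bounded, **kwargs,
    )


# ---------------------------------------------------------------------------
# draws archive
# ---------------------------------------------------------------------------

def save_draws(samples: PosteriorSamples, path: str | Path) -> None:
    meta = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "sites": list(samples.sites),
        "properties": list(samples.properties),
    }
    np.savez_compressed(
        path,
        zeta=samples.zeta, xi=samples.xi, phi=samples.phi, psi=samples.psi,
        theta2=samples.theta2, alpha=samples.alpha, rho=samples.rho,
        gamma=samples.gamma, lam=samples.lam, chain=samples.chain,
        n_obs=samples.n_obs,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_draws(path: str | Path) -> PosteriorSamples:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta.get("schema_version") != ARCHIVE_SCHEMA_VERSION:
            raise ValueError("unsupported draws-archive schema version")
        return PosteriorSamples(
            zeta=z["zeta"], xi=z["xi"], phi=z["phi"], psi=z["psi"],
            theta2=z["theta2"], alpha=z["alpha"], rho=z["rho"],
            gamma=z["gamma"], lam=z["lam"], chain=z["chain"],
            sites=tuple(meta["sites"]),
            properties=tuple(meta["properties"]),
            n_obs=z["n_obs"],
        )


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    inputs: dict[str, str | Path] | None = None,
) -> None:
    """JSON manifest sufficient to re-execute a run bit-identically
    (timing fields excepted)."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
        },
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
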