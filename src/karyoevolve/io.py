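"""Readers and writers for the interval, tree, and table formats the pipeline touches.

bedGraph and BED are 0-based half-open; GFF3 is 1-based inclusive and is
converted on input.  All tabular outputs are TSV with commented ``# key=value``
header lines carrying tool version, seed, and config hash so downstream runs
can verify provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import gffutils
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simdata import _natural_key

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_bed",
    "read_gff3",
    "write_table",
    "read_table",
    "write_ortholog_table",
    "read_ortholog_table",
    "PipelineConfig",
]


def read_bedgraph(path: Union[str, Path]) -> pd.DataFrame:
    """Parse a 4-column bedGraph (no track lines) into a sorted interval frame.

    Validates coordinates and depth per line and rejects overlapping
    intervals, naming the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, d = parts
            try:
                start, end, depth = int(s), int(e), float(d)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: reversed or empty interval {start}..{end}")
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {depth}")
            rows.append((chrom, start, end, depth, lineno))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "depth", "_line"])
    df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        bad = np.flatnonzero(starts[1:] < ends[:-1])
        if bad.size:
            line = int(grp["_line"].iloc[int(bad[0]) + 1])
            raise ValueError(f"{path}:{line}: interval overlaps the previous one on {chrom}")
    return df.drop(columns=["_line"])


def write_bedgraph(df: pd.DataFrame, path: Union[str, Path]) -> None:
    out = df[["chrom", "start", "end", "depth"]].copy()
    out.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: Union[str, Path]) -> dict[str, int]:
    """Two-column chrom\\tlength file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            chrom, length = parts[0], int(parts[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {chrom}")
            if chrom in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom}")
            sizes[chrom] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes, key=_natural_key):
            fh.write(f"{chrom}\t{int(sizes[chrom])}\n")


def read_gene_bed(path: Union[str, Path]) -> pd.DataFrame:
    """BED (>= 4 columns) of gene coordinates; strand stored, '.' if absent."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=range(12))
    df = df.dropna(axis=1, how="all")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: gene BED needs at least 4 columns")
    if df[3].isna().any():
        raise ValueError(f"{path}: gene BED rows missing the name column")
    strand = df[5].fillna(".").astype(str) if 5 in df.columns else "."
    out = pd.DataFrame(
        {
            "gene": df[3].astype(str),
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": strand,
        }
    )
    dup = out["gene"][out["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene ids: {', '.join(sorted(set(dup))[:5])}")
    return out


def read_gff3(path: Union[str, Path], feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Gene coordinates from GFF3, converted to 0-based half-open."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    rows = []
    for ft in feature_types:
        for feat in db.features_of_type(ft):
            gid = feat.attributes.get("ID", [feat.id])[0]
            rows.append((gid, feat.seqid, feat.start - 1, feat.end, feat.strand or "."))
    out = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    dup = out["gene"][out["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene ids: {', '.join(sorted(set(dup))[:5])}")
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_table(df: pd.DataFrame, path: Union[str, Path], meta: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    """TSV with '# key=value' provenance header lines."""
    with open(path, "w") as fh:
        fh.write(f"# karyoevolve={__version__}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: Union[str, Path], index_col=None) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=index_col)
    return df, meta


def write_ortholog_table(table: pd.DataFrame, path: Union[str, Path],
                         meta: Mapping[str, object] | None = None) -> None:
    write_table(table, path, meta=meta, index=True)


def read_ortholog_table(path: Union[str, Path]) -> pd.DataFrame:
    df, _ = read_table(path, index_col="ortholog_id")
    for col in df.columns:
        if col.endswith(":pos"):
            df[col] = df[col].astype(int)
        elif col.endswith(":chrom"):
            df[col] = df[col].astype(str)
    return df


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end demo pipeline, serializable to YAML."""

    tree: str = "(Tcas:0.0,((Pcha:1.0,Ppyr:1.0):0.5,(Caen:1.0,Dpon:1.0):0.5):0.2);"
    n_elements: int = 9
    genes_per_element: int = 200
    fusion_rate: float = 0.7
    fission_rate: float = 0.5
    shuffle_rate: float = 0.2
    window_size: int = 50_000
    genes_per_window: int = 4
    depth_f: float = 20.0
    depth_m: float = 30.0
    dispersion: float = 10.0
    theta: float = 0.6
    n_y_scaffolds: int = 2
    y_windows_each: int = 10
    x_threshold: float = 1.6
    y_threshold: float = 0.3
    min_windows: int = 3
    min_m_depth: float = 2.0
    normalization: str = "genome_median"
    min_orthologs: int = 20
    majority_frac: float = 0.5
    min_fpkm: float = 1.0
    fold: float = 2.0
    alpha: float = 0.05
    dc_mode: str = "complete"
    focal: str | None = None
    coverage_tip: str | None = None
    seed: int = 4
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.x_threshold <= 1.0:
            raise ValueError("x_threshold must exceed 1")
        if not 0.0 < self.y_threshold < 1.0:
            raise ValueError("y_threshold must lie in (0, 1)")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if not 0.0 <= self.shuffle_rate <= 1.0:
            raise ValueError("shuffle_rate must be in [0, 1]")
        if not 0.0 < self.majority_frac < 1.0:
            raise ValueError("majority_frac must lie in (0, 1)")
        if self.min_fpkm < 0:
            raise ValueError("min_fpkm must be >= 0")
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.normalization not in ("genome_median", "autosomal_median"):
            raise ValueError("unknown normalization mode")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**d)  # type: ignore[arg-type]

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
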