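"""File I/O for the pipeline's exchange formats.

Matrices travel as TSV with a header row and the feature id in the first
column; floats are formatted at 6 significant digits and missing cells are
empty fields. Gene sets use GMT, island references BED4 (0-based
half-open), site-level methylation the tab-separated bedMethyl dialect.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "write_bedmethyl",
    "read_labels",
    "write_labels",
    "read_gene_list",
    "read_island_gene_map",
]


def _fmt(v) -> str:
    if pd.isna(v):
        return ""
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return f"{v:.6g}"


def write_matrix(mat: pd.DataFrame, path, index_name: str | None = None):
    """Write a feature x sample matrix as TSV (6 significant digits)."""
    path = Path(path)
    name = index_name or mat.index.name or "feature"
    with open(path, "w") as fh:
        fh.write("\t".join([name, *map(str, mat.columns)]) + "\n")
        for idx, row in zip(mat.index, mat.to_numpy()):
            fh.write("\t".join([str(idx), *(_fmt(v) for v in row)]) + "\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix; empty cells become NaN; duplicate ids raise."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dup[:5]}")
    return mat


def write_gmt(genesets: Mapping[str, Sequence[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in genesets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_bed(islands: pd.DataFrame, path) -> None:
    """BED4 island reference; coordinates 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED)\n")
        for _, r in islands.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}"
                     f"\t{r['island_id']}\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                continue
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return pd.DataFrame(rows,
                        columns=["chrom", "start", "end", "island_id"])


def write_bedmethyl(records: pd.DataFrame, path,
                    mod_code: str = "m") -> None:
    """Write site records in the tab-separated bedMethyl dialect.

    Emits 11 tab-separated columns: chrom, start, end, mod code, score
    (= valid coverage), strand, thickStart, thickEnd, color, valid
    coverage, percent modified.
    """
    with open(path, "w") as fh:
        for _, r in records.iterrows():
            s, e = int(r["start"]), int(r["end"])
            cov = int(r["coverage"])
            fh.write("\t".join([
                str(r["chrom"]), str(s), str(e), mod_code, str(cov),
                str(r["strand"]), str(s), str(e), "255,0,0", str(cov),
                f"{r['percent']:.6g}",
            ]) + "\n")


def write_labels(labels: pd.DataFrame, path) -> None:
    cols = [c for c in ("group", "responder_count", "rank", "cluster",
                        "provenance") if c in labels.columns]
    labels[cols].to_csv(path, sep="\t", index_label="sample")


def read_labels(path) -> pd.DataFrame:
    lab = pd.read_csv(path, sep="\t", index_col="sample")
    if "group" not in lab.columns:
        raise ValueError("labels file must carry a 'group' column")
    return lab


def read_gene_list(path) -> List[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            g = line.strip().split("\t")[0]
            if g and not g.startswith("#"):
                out.append(g)
    return out


def read_island_gene_map(path) -> Dict[str, str]:
    """Two-column TSV: island_id <tab> gene symbol."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and not parts[0].startswith("#"):
                out[parts[0]] = parts[1]
    return out
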