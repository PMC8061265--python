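"""Readers and writers for the interchange formats.

All tables are UTF-8 delimited text, tab-separated by default with comma
accepted via ``sep=","``. Depth tracks are BedGraph (contig, start, end,
depth; 0-based half-open) or bare 3-column start/end/depth files; regions
are written as BED4+2. Every writer's output parses back through the
corresponding reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import AmplifiedRegion, DepthTrack
from .errors import BedParseError, TableFormatError
from .qpcr import CQ_COLUMNS, StandardCurve

#: Tokens mapped to an undetermined Cq on input.
UNDETERMINED_TOKENS = {"NA", "Undetermined", "undetermined", "NaN", ""}


def _read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    return pd.read_csv(path, sep=sep, dtype=str, comment="#", encoding="utf-8")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{what}: missing column(s) {missing}; found {list(df.columns)}"
        )


def read_cq_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a long Cq table; 'Undetermined'/'NA' map to NaN.

    Required columns: sample_id, gene_id, gene_role, dye, replicate, cq.
    Duplicate (sample_id, gene_id, replicate, dye) rows are rejected.
    """
    df = _read_table(path, sep)
    _require_columns(df, CQ_COLUMNS, "Cq table")
    df["cq"] = df["cq"].map(
        lambda v: np.nan if (pd.isna(v) or str(v).strip() in UNDETERMINED_TOKENS) else float(v)
    )
    df["replicate"] = df["replicate"].astype(int)
    if "template_conc" in df.columns:
        df["template_conc"] = pd.to_numeric(df["template_conc"], errors="coerce")
    key = ["sample_id", "gene_id", "replicate", "dye"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise TableFormatError(
            "duplicate well: "
            + ", ".join(f"{k}={first[k]}" for k in key)
        )
    bad = df["cq"].dropna() <= 0
    if bad.any():
        raise TableFormatError("determined cq values must be > 0")
    return df


def write_cq_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    out = df.copy()
    out["cq"] = out["cq"].map(lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep=sep, index=False)


def read_standard_curves(path: str | Path, sep: str = "\t") -> dict[str, StandardCurve]:
    """Read gene_id, log10_dilution, cq rows into per-gene standard curves."""
    df = _read_table(path, sep)
    _require_columns(df, ["gene_id", "log10_dilution", "cq"], "standard-curve table")
    out = {}
    for gene, grp in df.groupby("gene_id"):
        pts = [
            (float(r["log10_dilution"]), float(r["cq"])) for _, r in grp.iterrows()
        ]
        out[str(gene)] = StandardCurve(str(gene), pts)
    return out


def read_droplet_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = _read_table(path, sep)
    _require_columns(
        df, ["sample_id", "gene_id", "n_positive", "n_negative"], "droplet table"
    )
    df["n_positive"] = df["n_positive"].astype(int)
    df["n_negative"] = df["n_negative"].astype(int)
    return df


def read_depth(
    path: str | Path, format: str = "auto", sep: str = "\t", contig: str = "track"
) -> dict[str, DepthTrack]:
    """Read depth windows from BedGraph or 3-column start/end/depth text.

    Returns one DepthTrack per contig. Windows must be sorted, tiling and
    non-overlapping; violations raise with the offending line number.
    BedGraph is auto-detected by a 4-column body or a leading ``track``
    line; 3-column files take their contig name from ``contig``.
    """
    path = Path(path)
    if not path.exists():
        raise BedParseError(f"no such file: {path}")
    rows: list[tuple[str, int, int, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split(sep) if sep in line else line.split()
            try:
                if format == "bedgraph" or (format == "auto" and len(parts) >= 4):
                    rows.append(
                        (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                    )
                elif len(parts) == 3:
                    rows.append(
                        (contig, int(parts[0]), int(parts[1]), float(parts[2]))
                    )
                else:
                    raise ValueError(f"expected 3 or 4 columns, got {len(parts)}")
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise BedParseError(f"{path}: no depth windows")
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "depth"])
    tracks = {}
    for ctg, grp in df.groupby("contig", sort=False):
        starts = grp["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise BedParseError(f"{path}: windows for {ctg} are not sorted")
        tracks[str(ctg)] = DepthTrack(
            str(ctg), starts, grp["end"].to_numpy(), grp["depth"].to_numpy()
        )
    return tracks


def write_bedgraph(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tracks:
            for s, e, d in zip(t.starts, t.ends, t.depth):
                fh.write(f"{t.contig}\t{s}\t{e}\t{d:g}\n")


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of gene intervals (>= 4 columns, 0-based half-open)."""
    path = Path(path)
    if not path.exists():
        raise BedParseError(f"no such file: {path}")
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise BedParseError(f"{path}:{lineno}: BED needs >= 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end <= start")
            rows.append(
                {
                    "contig": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3],
                    "score": parts[4] if len(parts) > 4 else ".",
                    "strand": parts[5] if len(parts) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])


def write_regions_bed(regions: Sequence[AmplifiedRegion], path: str | Path) -> None:
    """Write amplified regions as BED4+2: name, fold (3 decimals), n_windows."""
    regions = sorted(regions, key=lambda r: (r.contig, r.start))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#contig\tstart\tend\tname\tfold\tn_windows\n")
        for i, r in enumerate(regions, start=1):
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\tamp{i}\t{r.fold:.3f}\t{r.n_windows}\n"
            )


def read_regions_bed(path: str | Path) -> list[AmplifiedRegion]:
    path = Path(path)
    regions = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise BedParseError(f"{path}:{lineno}: expected 6 columns")
            regions.append(
                AmplifiedRegion(
                    contig=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    fold=float(parts[4]),
                    n_windows=int(parts[5]),
                    n_masked_internal=0,
                )
            )
    return regions


def read_counts(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a genes x samples count matrix (first column = gene ids)."""
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")
    if df.index.duplicated().any():
        raise TableFormatError("duplicate gene ids in count matrix")
    return df


def read_sample_sheet(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = _read_table(path, sep)
    _require_columns(df, ["sample_id", "group"], "sample sheet")
    return df


def read_population_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    df = _read_table(path, sep)
    _require_columns(df, ["individual_id", "population_id"], "population map")
    return dict(zip(df["individual_id"], df["population_id"]))


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
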