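"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions centralized here:

* Peaks are BED-style 0-based half-open intervals; the ``summit`` column is an
  absolute 0-based position with ``start <= summit < end``.
* Gene TSS positions and promoter windows are 1-based inclusive.
* Matrices are TSV with the feature id in the first column and one column per
  sample; they are returned as :class:`pandas.DataFrame` with the feature id
  as index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InvalidArgumentError

PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "summit"]
GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]

#: label codes used in 8-bit mask PNGs
MASK_BACKGROUND, MASK_EPITHELIAL, MASK_STROMAL = 0, 1, 2


# ---------------------------------------------------------------------------
# matrices

def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise InvalidArgumentError(f"duplicate feature ids in {path}: {dupes}")
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# peaks

def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a peak table, either a headered TSV or a BED6+1 file.

    The BED6+1 layout is chrom/start/end/name/score/strand plus a 7th column
    holding the summit offset relative to ``start``.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if "peak_id" in first:
        peaks = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(PEAK_COLUMNS) - set(peaks.columns)
        if missing:
            raise InvalidArgumentError(f"peak TSV missing columns {sorted(missing)}")
        peaks = peaks[PEAK_COLUMNS]
    else:
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand", "summit_offset"],
            dtype={"chrom": str},
        )
        peaks = pd.DataFrame({
            "peak_id": bed["name"].astype(str),
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "summit": (bed["start"] + bed["summit_offset"]).astype(int),
        })
    validate_peaks(peaks)
    return peaks


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", index=False)


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write peaks as BED6+1 (7th column = summit offset from start)."""
    bed = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["start"],
        "end": peaks["end"],
        "name": peaks["peak_id"],
        "score": 0,
        "strand": ".",
        "summit_offset": peaks["summit"] - peaks["start"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def validate_peaks(peaks: pd.DataFrame) -> None:
    bad = peaks[(peaks["start"] >= peaks["end"])
                | (peaks["summit"] < peaks["start"])
                | (peaks["summit"] >= peaks["end"])]
    if len(bad):
        raise InvalidArgumentError(
            f"{len(bad)} peaks violate start < end and start <= summit < end "
            f"(first offender: {bad.iloc[0]['peak_id']})")
    if peaks["peak_id"].duplicated().any():
        raise InvalidArgumentError("duplicate peak ids")


# ---------------------------------------------------------------------------
# genes

def read_genes(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise InvalidArgumentError(f"gene TSV missing columns {sorted(missing)}")
    genes = genes[GENE_COLUMNS].copy()
    genes["tss"] = genes["tss"].astype(int)
    validate_genes(genes)
    return genes


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_genes(genes: pd.DataFrame) -> None:
    if not genes["strand"].isin(["+", "-"]).all():
        raise InvalidArgumentError("gene strand must be '+' or '-'")
    if (genes["tss"] < 1).any():
        raise InvalidArgumentError("TSS positions are 1-based and must be >= 1")
    if genes["gene_id"].duplicated().any():
        raise InvalidArgumentError("duplicate gene ids")


def gff3_to_genes(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Extract a gene_id/chrom/tss/strand table from a GFF3 file.

    TSS is the 5' end of the feature: ``start`` on '+', ``end`` on '-'
    (GFF3 coordinates are already 1-based inclusive).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != feature_type:
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            gene_id = attr.get("gene_id") or attr.get("ID") or attr.get("Name")
            if gene_id is None:
                raise InvalidArgumentError(f"GFF3 {feature_type} without gene_id/ID/Name: {line!r}")
            tss = int(start) if strand == "+" else int(end)
            rows.append((gene_id, chrom, tss, strand))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    validate_genes(genes)
    return genes


# ---------------------------------------------------------------------------
# cohort / survival tables

def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in cohort.columns or "proportion" not in cohort.columns:
        raise InvalidArgumentError("cohort TSV needs sample_id and proportion columns")
    if ((cohort["proportion"] < 0) | (cohort["proportion"] > 1)).any():
        raise InvalidArgumentError("proportions must lie in [0, 1]")
    if cohort["sample_id"].duplicated().any():
        raise InvalidArgumentError("duplicate sample ids in cohort")
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["sample_id", "proportion", "group"] if c in cohort.columns]
    cohort[cols].to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "time_days", "event"} - set(surv.columns)
    if missing:
        raise InvalidArgumentError(f"survival TSV missing columns {sorted(missing)}")
    if (surv["time_days"] <= 0).any():
        raise InvalidArgumentError("survival times must be > 0")
    if not surv["event"].isin([0, 1]).all():
        raise InvalidArgumentError("event indicator must be 0 or 1")
    return surv


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    surv[["sample_id", "time_days", "event"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, genes = fields[0], {g for g in fields[2:] if g}
            if not genes:
                continue
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# masks

def read_mask_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit label PNG; labels must be {0, 1, 2}."""
    mask = np.asarray(Image.open(path))
    unknown = np.setdiff1d(np.unique(mask), [MASK_BACKGROUND, MASK_EPITHELIAL, MASK_STROMAL])
    if unknown.size:
        raise InvalidArgumentError(f"unknown label values in mask {path}: {unknown.tolist()}")
    return mask.astype(np.uint8)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# JSON helpers

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
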