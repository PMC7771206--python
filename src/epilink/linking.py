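"""Assign peaks to candidate target genes and collapse links to a gene table.

Two link kinds:

* promoter — the peak summit lies 100-1000 bp upstream of a gene's TSS
  (strand-aware, 1-based inclusive window);
* distal — the summit lies within 500 kbp of a TSS and the accessibility of
  the peak correlates with the gene's expression at BH FDR <= 0.01, with
  copy-number-driven and promoter-overlapping links filtered out.

Peaks use 0-based half-open coordinates; summits are converted to 1-based
positions before any comparison with TSS/window coordinates.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .screen import align_samples, bh_fdr

log = logging.getLogger(__name__)

PROMOTER_UPSTREAM_FAR = 1000
PROMOTER_UPSTREAM_NEAR = 100
MAX_DISTAL_DISTANCE = 500_000
DISTAL_FDR_CUTOFF = 0.01
CNV_ATTENUATION = 0.5

LINK_COLUMNS = ["peak_id", "gene_id", "kind", "distance", "rho", "fdr", "filters"]


def promoter_window(tss: int, strand: str,
                    far: int = PROMOTER_UPSTREAM_FAR,
                    near: int = PROMOTER_UPSTREAM_NEAR) -> tuple[int, int]:
    """1-based inclusive promoter interval upstream of the TSS.

    '+' strand: [tss - far, tss - near]; '-' strand: [tss + near, tss + far].
    Windows running off the chromosome start are truncated at 1.
    """
    if tss < 1:
        raise InvalidArgumentError("TSS is 1-based and must be >= 1")
    if strand == "+":
        lo, hi = tss - far, tss - near
    elif strand == "-":
        lo, hi = tss + near, tss + far
    else:
        raise InvalidArgumentError(f"strand must be '+' or '-', got {strand!r}")
    if lo < 1:
        warnings.warn(f"promoter window for tss={tss} truncated at position 1")
        lo = 1
    return lo, hi


def _summits_1based(peaks: pd.DataFrame) -> np.ndarray:
    return peaks["summit"].to_numpy() + 1


def assign_promoter_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                          far: int = PROMOTER_UPSTREAM_FAR,
                          near: int = PROMOTER_UPSTREAM_NEAR,
                          keep_all: bool = False) -> pd.DataFrame:
    """Promoter links: peak summit inside a gene's upstream window.

    A summit hitting several genes' windows is assigned to the gene with the
    nearest TSS (ties broken by lexicographic gene_id) unless ``keep_all``.
    Searches by inverting the window test: a summit s sits in a '+' gene's
    window iff the TSS lies in [s + near, s + far], and mirrored for '-'.
    """
    rows = []
    summits = _summits_1based(peaks)
    for strand in ("+", "-"):
        sub = genes[genes["strand"] == strand]
        for chrom, chrom_genes in sub.groupby("chrom", sort=False):
            mask = (peaks["chrom"] == chrom).to_numpy()
            if not mask.any() or chrom_genes.empty:
                continue
            tss_sorted = chrom_genes.sort_values(["tss", "gene_id"])
            tss = tss_sorted["tss"].to_numpy()
            gids = tss_sorted["gene_id"].to_numpy()
            s = summits[mask]
            pids = peaks.loc[mask, "peak_id"].to_numpy()
            if strand == "+":
                lo, hi = s + near, s + far
            else:
                lo, hi = s - far, s - near
            starts = np.searchsorted(tss, lo, side="left")
            stops = np.searchsorted(tss, hi, side="right")
            for pid, s1, a, b in zip(pids, s, starts, stops):
                for j in range(a, b):
                    rows.append((pid, gids[j], "promoter", int(abs(s1 - tss[j]))))
    links = pd.DataFrame(rows, columns=["peak_id", "gene_id", "kind", "distance"])
    if not keep_all and len(links):
        links = (links.sort_values(["peak_id", "distance", "gene_id"])
                 .groupby("peak_id", as_index=False).first())
    links["rho"] = np.nan
    links["fdr"] = np.nan
    links["filters"] = ""
    return links.reset_index(drop=True)[LINK_COLUMNS]


def candidate_distal_pairs(peaks: pd.DataFrame, genes: pd.DataFrame,
                           max_dist: int = MAX_DISTAL_DISTANCE) -> pd.DataFrame:
    """All same-chromosome (peak, gene) pairs with |summit - TSS| < max_dist."""
    if max_dist <= 0:
        raise InvalidArgumentError("max_dist must be > 0")
    rows = []
    summits = _summits_1based(peaks)
    for chrom, chrom_genes in genes.groupby("chrom", sort=False):
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        tss_sorted = chrom_genes.sort_values(["tss", "gene_id"])
        tss = tss_sorted["tss"].to_numpy()
        gids = tss_sorted["gene_id"].to_numpy()
        s = summits[mask]
        pids = peaks.loc[mask, "peak_id"].to_numpy()
        # strict bound: |s - tss| < max_dist
        starts = np.searchsorted(tss, s - max_dist, side="right")
        stops = np.searchsorted(tss, s + max_dist, side="left")
        for pid, s1, a, b in zip(pids, s, starts, stops):
            for j in range(a, b):
                rows.append((pid, gids[j], int(abs(s1 - tss[j]))))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def _rank_matrix(df: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(stats.rankdata(df.to_numpy(dtype=float), axis=1),
                        index=df.index, columns=df.columns)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    du, dv = np.linalg.norm(u), np.linalg.norm(v)
    if du == 0 or dv == 0:
        return np.nan
    return float(u @ v / (du * dv))


def _partial_pearson(u: np.ndarray, v: np.ndarray, c: np.ndarray) -> float:
    r_uv, r_uc, r_vc = _pearson(u, v), _pearson(u, c), _pearson(v, c)
    if any(np.isnan(r) for r in (r_uv, r_uc, r_vc)):
        return np.nan
    denom = np.sqrt(max(1e-12, (1 - r_uc ** 2) * (1 - r_vc ** 2)))
    return (r_uv - r_uc * r_vc) / denom


def link_distal(pairs: pd.DataFrame, acc: pd.DataFrame, expr: pd.DataFrame,
                cn: pd.DataFrame | None = None, fdr_cut: float = DISTAL_FDR_CUTOFF,
                cnv_attenuation: float = CNV_ATTENUATION,
                promoter_windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Correlation-supported distal links with CNV and promoter-overlap filters.

    For every candidate pair, rho = Spearman(peak accessibility, gene
    expression) over the shared samples; BH is applied across all tested
    pairs. A surviving link must have fdr <= fdr_cut and no filter flags:

    * ``cnv_driven`` — copy-number adjustment attenuates the rank correlation
      below ``cnv_attenuation`` x its marginal value;
    * ``promoter_overlap`` — the peak summit lies in any gene's promoter
      window (pass the relevant peaks+genes via ``promoter_windows`` as a
      table with columns chrom, lo, hi).

    Returns the full annotated pair table; surviving links are the subset
    with ``survives``.
    """
    if pairs.empty:
        return pd.DataFrame(columns=LINK_COLUMNS + ["survives"])
    shared = sorted(set(acc.columns) & set(expr.columns))
    if len(shared) < 3:
        raise InvalidArgumentError(f"accessibility and expression share only {len(shared)} samples")
    if cn is not None:
        shared = sorted(set(shared) & set(cn.columns))
        if len(shared) < 3:
            raise InvalidArgumentError("copy-number matrix shares < 3 samples")
    missing_p = set(pairs["peak_id"]) - set(acc.index)
    missing_g = set(pairs["gene_id"]) - set(expr.index)
    if missing_p or missing_g:
        raise InvalidArgumentError(
            f"pairs reference unknown features: peaks {sorted(missing_p)[:3]} "
            f"genes {sorted(missing_g)[:3]}")
    if cn is None:
        log.warning("no copy-number matrix given: cnv_driven filter skipped")

    acc_r = _rank_matrix(acc.loc[sorted(set(pairs['peak_id'])), shared])
    expr_r = _rank_matrix(expr.loc[sorted(set(pairs['gene_id'])), shared])
    cn_r = _rank_matrix(cn[shared]) if cn is not None else None

    rhos, partials = [], []
    for pid, gid in zip(pairs["peak_id"], pairs["gene_id"]):
        u = acc_r.loc[pid].to_numpy()
        v = expr_r.loc[gid].to_numpy()
        rho = _pearson(u, v)
        rhos.append(rho)
        if cn_r is not None and pid in cn_r.index:
            partials.append(_partial_pearson(u, v, cn_r.loc[pid].to_numpy()))
        else:
            partials.append(np.nan)
    rhos = np.asarray(rhos)
    partials = np.asarray(partials)

    n = len(shared)
    testable = ~np.isnan(rhos)
    p = np.full(len(rhos), np.nan)
    denom = np.maximum(1.0 - rhos[testable] ** 2, 1e-300)
    t = rhos[testable] * np.sqrt((n - 2) / denom)
    p[testable] = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    fdr = np.full(len(rhos), np.nan)
    fdr[testable] = bh_fdr(p[testable])

    cnv_flag = np.zeros(len(rhos), dtype=bool)
    has_partial = ~np.isnan(partials)
    cnv_flag[has_partial] = (np.abs(partials[has_partial])
                             < cnv_attenuation * np.abs(rhos[has_partial]))

    overlap_flag = np.zeros(len(rhos), dtype=bool)
    if promoter_windows is not None and len(promoter_windows):
        summit_pos = pairs["summit_1based"].to_numpy() if "summit_1based" in pairs \
            else None
        if summit_pos is None:
            raise InvalidArgumentError(
                "promoter_windows given but pairs lack summit_1based/chrom columns")
        for chrom, win in promoter_windows.groupby("chrom", sort=False):
            sel = (pairs["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            lo = win["lo"].to_numpy()
            hi = win["hi"].to_numpy()
            s = summit_pos[sel]
            overlap_flag[sel] = ((s[:, None] >= lo[None, :])
                                 & (s[:, None] <= hi[None, :])).any(axis=1)

    filters = []
    for c, o in zip(cnv_flag, overlap_flag):
        tags = [t for t, f in (("cnv_driven", c), ("promoter_overlap", o)) if f]
        filters.append(",".join(tags))
    out = pairs[["peak_id", "gene_id", "distance"]].copy()
    out["kind"] = "distal"
    out["rho"] = rhos
    out["fdr"] = fdr
    out["filters"] = filters
    out["survives"] = testable & (fdr <= fdr_cut) & ~cnv_flag & ~overlap_flag
    return out[LINK_COLUMNS + ["survives"]].reset_index(drop=True)


def build_promoter_windows(genes: pd.DataFrame, far: int = PROMOTER_UPSTREAM_FAR,
                           near: int = PROMOTER_UPSTREAM_NEAR) -> pd.DataFrame:
    """Promoter windows (chrom, lo, hi; 1-based inclusive) for all genes."""
    rows = []
    for g in genes.itertuples(index=False):
        lo, hi = promoter_window(int(g.tss), g.strand, far=far, near=near)
        rows.append((g.chrom, lo, hi))
    return pd.DataFrame(rows, columns=["chrom", "lo", "hi"])


def annotate_pairs_with_summits(pairs: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Attach chrom and 1-based summit columns needed by the overlap filter."""
    coords = peaks.set_index("peak_id")
    out = pairs.copy()
    out["chrom"] = coords.loc[out["peak_id"], "chrom"].to_numpy()
    out["summit_1based"] = coords.loc[out["peak_id"], "summit"].to_numpy() + 1
    return out


def collapse_targets(promoter_links: pd.DataFrame, distal_links: pd.DataFrame,
                     expr: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse surviving links into one signed target gene per distinct gene.

    The sign is the sign of Spearman(expression, proportion) over the cohort
    samples; an exact zero is labeled positive by convention; genes missing
    from the expression matrix keep sign 'unknown'.
    """
    frames = []
    if len(promoter_links):
        frames.append(promoter_links[["peak_id", "gene_id", "kind"]])
    if len(distal_links):
        surv = distal_links[distal_links["survives"]] if "survives" in distal_links \
            else distal_links
        frames.append(surv[["peak_id", "gene_id", "kind"]])
    if not frames:
        return pd.DataFrame(columns=["gene_id", "sign", "n_links", "supporting_links"])
    links = pd.concat(frames, ignore_index=True)

    rows = []
    for gene_id, sub in links.groupby("gene_id", sort=True):
        if gene_id in expr.index:
            mat, coh = align_samples(expr.loc[[gene_id]], cohort)
            e = mat.to_numpy(dtype=float)[0]
            y = coh["proportion"].to_numpy(dtype=float)
            if np.unique(e).size < 2 or np.unique(y).size < 2:
                sign = "unknown"
            else:
                rho = _pearson(stats.rankdata(e), stats.rankdata(y))
                if rho == 0.0:
                    log.warning("gene %s has exactly zero correlation; labeled positive", gene_id)
                sign = "positive" if rho >= 0 else "negative"
        else:
            log.warning("gene %s absent from expression matrix; sign unknown", gene_id)
            sign = "unknown"
        supporting = ";".join(f"{r.peak_id}:{r.kind}" for r in sub.itertuples(index=False))
        rows.append((gene_id, sign, len(sub), supporting))
    return pd.DataFrame(rows, columns=["gene_id", "sign", "n_links", "supporting_links"])
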