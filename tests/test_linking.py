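"""Promoter/distal linking against exhaustive all-pairs oracles."""

import numpy as np
import pandas as pd
import pytest

from epilink.errors import InvalidArgumentError
from epilink.linking import (
    annotate_pairs_with_summits,
    assign_promoter_peaks,
    build_promoter_windows,
    candidate_distal_pairs,
    collapse_targets,
    link_distal,
    promoter_window,
)
from epilink.synthetic import (
    GenomeSpec,
    generate_gene_annotation,
    generate_peak_atlas,
)

from conftest import toy_cohort


# ---------------------------------------------------------------------------
# brute-force oracles (independent double loops over the stated rules)

def oracle_promoter_links(peaks, genes, far=1000, near=100):
    hits = []
    for p in peaks.itertuples(index=False):
        s1 = p.summit + 1  # 1-based summit
        for g in genes.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            if g.strand == "+":
                lo, hi = max(1, g.tss - far), g.tss - near
            else:
                lo, hi = g.tss + near, g.tss + far
            if lo <= s1 <= hi:
                hits.append((p.peak_id, g.gene_id, abs(s1 - g.tss)))
    # nearest TSS per peak, lexicographic gene_id tie-break
    best = {}
    for pid, gid, d in hits:
        cur = best.get(pid)
        if cur is None or (d, gid) < cur:
            best[pid] = (d, gid)
    return {(pid, gid) for pid, (d, gid) in best.items()}


def oracle_distal_pairs(peaks, genes, max_dist=500_000):
    out = set()
    for p in peaks.itertuples(index=False):
        for g in genes.itertuples(index=False):
            if g.chrom == p.chrom and abs((p.summit + 1) - g.tss) < max_dist:
                out.add((p.peak_id, g.gene_id, abs((p.summit + 1) - g.tss)))
    return out


# ---------------------------------------------------------------------------
# promoter_window

def test_window_plus_strand():
    assert promoter_window(10_000, "+") == (9000, 9900)


def test_window_minus_strand():
    assert promoter_window(10_000, "-") == (10_100, 11_000)


def test_window_truncated_at_one():
    with pytest.warns(UserWarning):
        assert promoter_window(500, "+") == (1, 400)


def test_window_rejects_bad_input():
    with pytest.raises(InvalidArgumentError):
        promoter_window(0, "+")
    with pytest.raises(InvalidArgumentError):
        promoter_window(100, "x")


# ---------------------------------------------------------------------------
# assign_promoter_peaks

def _toy_peak(peak_id, chrom, summit, width=501):
    start = max(0, summit - width // 2)
    return {"peak_id": peak_id, "chrom": chrom, "start": start,
            "end": start + width, "summit": summit}


def test_promoter_hit_inside_window():
    # summit at 0-based 9499 -> 1-based 9500, inside [9000, 9900]
    peaks = pd.DataFrame([_toy_peak("p1", "c", 9499)])
    genes = pd.DataFrame([{"gene_id": "g1", "chrom": "c", "tss": 10_000, "strand": "+"}])
    links = assign_promoter_peaks(peaks, genes)
    assert list(zip(links["peak_id"], links["gene_id"])) == [("p1", "g1")]
    assert links["kind"].iloc[0] == "promoter"


def test_promoter_miss_in_proximal_gap():
    # 1-based 9950 is inside the excluded 100 bp proximal gap
    peaks = pd.DataFrame([_toy_peak("p1", "c", 9949)])
    genes = pd.DataFrame([{"gene_id": "g1", "chrom": "c", "tss": 10_000, "strand": "+"}])
    assert len(assign_promoter_peaks(peaks, genes)) == 0


def test_promoter_tie_break_nearest_tss():
    peaks = pd.DataFrame([_toy_peak("p1", "c", 9499)])
    genes = pd.DataFrame([
        {"gene_id": "g_far", "chrom": "c", "tss": 10_400, "strand": "+"},
        {"gene_id": "g_near", "chrom": "c", "tss": 10_000, "strand": "+"},
    ])
    links = assign_promoter_peaks(peaks, genes)
    assert list(links["gene_id"]) == ["g_near"]
    both = assign_promoter_peaks(peaks, genes, keep_all=True)
    assert set(both["gene_id"]) == {"g_far", "g_near"}


def test_promoter_matches_oracle_on_toy_genomes():
    genome = GenomeSpec((("c1", 200_000), ("c2", 150_000)))
    for seed in range(5):
        peaks = generate_peak_atlas(genome, n_peaks=40, width=301, seed=seed)
        genes = generate_gene_annotation(genome, n_genes=25, seed=seed + 50)
        # densify: drop genes onto peak neighborhoods so windows actually hit
        rng = np.random.default_rng(seed)
        for i in range(10):
            j = rng.integers(0, len(genes))
            k = rng.integers(0, len(peaks))
            offset = rng.integers(-1200, 1200)
            genes.loc[genes.index[j], "chrom"] = peaks.iloc[k]["chrom"]
            genes.loc[genes.index[j], "tss"] = max(1, peaks.iloc[k]["summit"] + offset)
        links = assign_promoter_peaks(peaks, genes)
        got = set(zip(links["peak_id"], links["gene_id"]))
        assert got == oracle_promoter_links(peaks, genes)


def test_strand_mirror_invariance():
    length = 300_000
    genome = GenomeSpec((("c", length),))
    peaks = generate_peak_atlas(genome, n_peaks=30, width=301, seed=3)
    genes = generate_gene_annotation(genome, n_genes=30, seed=4)
    rng = np.random.default_rng(5)
    for i in range(12):  # place some genes near summits
        j, k = rng.integers(0, len(genes)), rng.integers(0, len(peaks))
        genes.loc[genes.index[j], "tss"] = max(
            1, int(peaks.iloc[k]["summit"]) + int(rng.integers(-1200, 1200)))

    mirrored_peaks = peaks.copy()
    mirrored_peaks["start"] = length - peaks["end"]
    mirrored_peaks["end"] = length - peaks["start"]
    mirrored_peaks["summit"] = length - 1 - peaks["summit"]
    mirrored_genes = genes.copy()
    mirrored_genes["tss"] = length + 1 - genes["tss"]
    mirrored_genes["strand"] = genes["strand"].map({"+": "-", "-": "+"})

    orig = set(zip(*[assign_promoter_peaks(peaks, genes)[c]
                     for c in ("peak_id", "gene_id")]))
    mirr = set(zip(*[assign_promoter_peaks(mirrored_peaks, mirrored_genes)[c]
                     for c in ("peak_id", "gene_id")]))
    assert orig == mirr

    d_orig = oracle_distal_pairs(peaks, genes, 50_000)
    d_mirr = oracle_distal_pairs(mirrored_peaks, mirrored_genes, 50_000)
    assert {(p, g) for p, g, _ in d_orig} == {(p, g) for p, g, _ in d_mirr}


# ---------------------------------------------------------------------------
# candidate_distal_pairs

def test_distal_pair_within_bound():
    peaks = pd.DataFrame([_toy_peak("p1", "c", 999)])  # 1-based 1000
    genes = pd.DataFrame([{"gene_id": "g1", "chrom": "c", "tss": 400_000, "strand": "+"}])
    pairs = candidate_distal_pairs(peaks, genes)
    assert len(pairs) == 1
    assert pairs["distance"].iloc[0] == 399_000


def test_distal_pair_beyond_bound_excluded():
    peaks = pd.DataFrame([_toy_peak("p1", "c", 999)])
    genes = pd.DataFrame([{"gene_id": "g1", "chrom": "c", "tss": 600_000, "strand": "+"}])
    assert len(candidate_distal_pairs(peaks, genes)) == 0


def test_distal_bound_is_strict():
    peaks = pd.DataFrame([_toy_peak("p1", "c", 999)])
    genes = pd.DataFrame([
        {"gene_id": "exact", "chrom": "c", "tss": 501_000, "strand": "+"},   # d = 500000
        {"gene_id": "inside", "chrom": "c", "tss": 500_999, "strand": "+"},  # d = 499999
    ])
    pairs = candidate_distal_pairs(peaks, genes)
    assert set(pairs["gene_id"]) == {"inside"}


def test_distal_pairs_match_oracle():
    genome = GenomeSpec((("c1", 2_000_000), ("c2", 1_500_000)))
    for seed in range(4):
        peaks = generate_peak_atlas(genome, n_peaks=30, width=301, seed=seed)
        genes = generate_gene_annotation(genome, n_genes=20, seed=seed + 9)
        pairs = candidate_distal_pairs(peaks, genes)
        got = set(zip(pairs["peak_id"], pairs["gene_id"], pairs["distance"]))
        assert got == oracle_distal_pairs(peaks, genes)


# ---------------------------------------------------------------------------
# link_distal

def test_link_distal_planted_pair_survives(bundle):
    planted = [l for l in bundle.truth.links if l["kind"] == "distal"
               and not l["cn_driven"]]
    sig_peaks = bundle.peaks[bundle.peaks["peak_id"].isin(
        bundle.truth.planted_peak_ids)].reset_index(drop=True)
    pairs = annotate_pairs_with_summits(
        candidate_distal_pairs(sig_peaks, bundle.genes), sig_peaks)
    links = link_distal(pairs, bundle.accessibility, bundle.expression,
                        cn=bundle.copy_number,
                        promoter_windows=build_promoter_windows(bundle.genes))
    surviving = set(zip(links.loc[links["survives"], "peak_id"],
                        links.loc[links["survives"], "gene_id"]))
    for l in planted:
        assert (l["peak_id"], l["gene_id"]) in surviving
    # every surviving link satisfies all three predicates
    surv = links[links["survives"]]
    assert (surv["fdr"] <= 0.01).all()
    assert (surv["filters"] == "").all()
    assert (surv["distance"] < 500_000).all()


def test_link_distal_cn_driven_flagged(bundle):
    cn_links = [l for l in bundle.truth.links if l["cn_driven"]]
    sig_peaks = bundle.peaks[bundle.peaks["peak_id"].isin(
        bundle.truth.planted_peak_ids)].reset_index(drop=True)
    pairs = annotate_pairs_with_summits(
        candidate_distal_pairs(sig_peaks, bundle.genes), sig_peaks)
    links = link_distal(pairs, bundle.accessibility, bundle.expression,
                        cn=bundle.copy_number,
                        promoter_windows=build_promoter_windows(bundle.genes))
    for l in cn_links:
        row = links[(links["peak_id"] == l["peak_id"])
                    & (links["gene_id"] == l["gene_id"])].iloc[0]
        assert "cnv_driven" in row["filters"]
        assert not row["survives"]


def test_link_distal_promoter_overlap_flagged():
    # one peak whose summit sits in another gene's promoter window
    peaks = pd.DataFrame([_toy_peak("p1", "c", 9499)])
    genes = pd.DataFrame([
        {"gene_id": "host", "chrom": "c", "tss": 10_000, "strand": "+"},
        {"gene_id": "distal_target", "chrom": "c", "tss": 60_000, "strand": "+"},
    ])
    rng = np.random.default_rng(0)
    samples = [f"S{i}" for i in range(20)]
    base = rng.standard_normal(20)
    acc = pd.DataFrame([base], index=["p1"], columns=samples)
    expr = pd.DataFrame([base + 0.01 * rng.standard_normal(20),
                         rng.standard_normal(20)],
                        index=["distal_target", "host"], columns=samples)
    pairs = annotate_pairs_with_summits(candidate_distal_pairs(peaks, genes), peaks)
    links = link_distal(pairs, acc, expr,
                        promoter_windows=build_promoter_windows(genes))
    target_row = links[links["gene_id"] == "distal_target"].iloc[0]
    assert "promoter_overlap" in target_row["filters"]
    assert not target_row["survives"]


def test_link_distal_planted_among_nulls():
    # a perfectly coupled pair among 500 null pairs survives BH at 0.01
    rng = np.random.default_rng(1)
    samples = [f"S{i}" for i in range(30)]
    signal = rng.standard_normal(30)
    acc_rows = {"peak_hit": signal}
    expr_rows = {"gene_hit": signal}
    pair_rows = [("peak_hit", "gene_hit", 10_000)]
    for i in range(500):
        acc_rows[f"peak_n{i}"] = rng.standard_normal(30)
        expr_rows[f"gene_n{i}"] = rng.standard_normal(30)
        pair_rows.append((f"peak_n{i}", f"gene_n{i}", 10_000))
    acc = pd.DataFrame(acc_rows).T
    acc.columns = samples
    expr = pd.DataFrame(expr_rows).T
    expr.columns = samples
    pairs = pd.DataFrame(pair_rows, columns=["peak_id", "gene_id", "distance"])
    links = link_distal(pairs, acc, expr)
    hit = links[links["gene_id"] == "gene_hit"].iloc[0]
    assert hit["survives"] and hit["fdr"] <= 0.01
    assert links["survives"].sum() <= 3  # essentially only the planted pair


def test_link_distal_requires_shared_samples(bundle):
    pairs = pd.DataFrame([("p", "g", 1)], columns=["peak_id", "gene_id", "distance"])
    acc = pd.DataFrame([[1.0]], index=["p"], columns=["only"])
    expr = pd.DataFrame([[1.0]], index=["g"], columns=["other"])
    with pytest.raises(InvalidArgumentError):
        link_distal(pairs, acc, expr)


# ---------------------------------------------------------------------------
# collapse_targets

def test_collapse_dedups_and_counts_links(bundle):
    prom = pd.DataFrame({
        "peak_id": ["p1", "p2", "p3"],
        "gene_id": ["g1", "g1", "g1"],
        "kind": "promoter", "distance": 1, "rho": np.nan, "fdr": np.nan,
        "filters": ""})
    targets = collapse_targets(prom, pd.DataFrame(), bundle.expression,
                               bundle.cohort)
    assert len(targets) == 1
    assert targets["n_links"].iloc[0] == 3
    assert targets["sign"].iloc[0] == "unknown"  # g1 not in expression


def test_collapse_sign_from_proportion():
    cohort = toy_cohort(np.linspace(0.05, 0.95, 12))
    samples = cohort["sample_id"].tolist()
    expr = pd.DataFrame(
        [np.linspace(0, 1, 12), np.linspace(1, 0, 12)],
        index=["g_pos", "g_neg"], columns=samples)
    prom = pd.DataFrame({
        "peak_id": ["p1", "p2"], "gene_id": ["g_pos", "g_neg"],
        "kind": "promoter", "distance": 1, "rho": np.nan, "fdr": np.nan,
        "filters": ""})
    targets = collapse_targets(prom, pd.DataFrame(), expr, cohort)
    signs = dict(zip(targets["gene_id"], targets["sign"]))
    assert signs == {"g_pos": "positive", "g_neg": "negative"}


def test_collapse_counts_match_truth(bundle):
    from epilink.screen import screen_peaks
    res = screen_peaks(bundle.accessibility, bundle.cohort)
    sig_peaks = bundle.peaks[bundle.peaks["peak_id"].isin(
        res.loc[res["significant"], "peak_id"])].reset_index(drop=True)
    prom = assign_promoter_peaks(sig_peaks, bundle.genes)
    pairs = annotate_pairs_with_summits(
        candidate_distal_pairs(sig_peaks, bundle.genes), sig_peaks)
    distal = link_distal(pairs, bundle.accessibility, bundle.expression,
                         cn=bundle.copy_number,
                         promoter_windows=build_promoter_windows(bundle.genes))
    targets = collapse_targets(prom, distal, bundle.expression, bundle.cohort)
    # no target appears twice; link counts add up
    assert targets["gene_id"].is_unique
    assert targets["n_links"].sum() == len(prom) + int(distal["survives"].sum())
    # all non-cn planted genes recovered
    expected = {l["gene_id"] for l in bundle.truth.links if not l["cn_driven"]}
    assert expected <= set(targets["gene_id"])
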