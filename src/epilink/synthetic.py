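"""Synthetic cohorts with planted peak-phenotype and peak-gene structure.

Every generator is deterministic given its seed. The generators emit the same
plain-text formats the pipeline reads, so an end-to-end run needs no external
data. The statistical constructions are deliberately simple:

* sample proportions come from a Beta distribution whose parameters are solved
  so that the sub-0.5 mass equals ``low_fraction``;
* planted accessibility rows are a Gaussian rank-mixture with the phenotype's
  normal scores — the mixing weight is chosen with the arcsine correction so
  the population Spearman correlation equals the requested strength;
* survival times follow an exponential proportional-hazards model with
  independent exponential censoring tuned to the requested censoring rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .errors import InvalidArgumentError
from .io import MASK_BACKGROUND, MASK_EPITHELIAL, MASK_STROMAL


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class GenomeSpec:
    """A toy genome: ordered (name, length-in-bp) pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("chromosome names must be unique")
        if any(c[1] <= 0 for c in self.chromosomes):
            raise InvalidArgumentError("chromosome lengths must be > 0")

    @property
    def total_length(self) -> int:
        return sum(c[1] for c in self.chromosomes)


DEFAULT_GENOME = GenomeSpec((("chrA", 10_000_000), ("chrB", 10_000_000)))


@dataclass(frozen=True)
class PlantedEffect:
    """A peak with a planted monotone association to the phenotype."""

    peak_id: str
    direction: int  # +1 or -1
    strength: float  # target |Spearman rho| in [0, 1]
    linked_gene: str | None = None
    cn_driven: bool = False

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise InvalidArgumentError(f"direction must be +1/-1, got {self.direction}")
        if not 0.0 <= self.strength <= 1.0:
            raise InvalidArgumentError(f"strength must be in [0,1], got {self.strength}")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated bundle, for recovery scoring."""

    effects: list[PlantedEffect] = field(default_factory=list)
    links: list[dict] = field(default_factory=list)  # peak_id, gene_id, kind, cn_driven
    prognostic: list[tuple[str, float]] = field(default_factory=list)
    proportion_coef: float = 0.0

    @property
    def planted_peak_ids(self) -> set[str]:
        return {e.peak_id for e in self.effects}

    @property
    def target_gene_ids(self) -> set[str]:
        return {l["gene_id"] for l in self.links}

    def to_dict(self) -> dict:
        return {
            "effects": [vars(e) for e in self.effects],
            "links": self.links,
            "prognostic": [[g, float(c)] for g, c in self.prognostic],
            "proportion_coef": self.proportion_coef,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            effects=[PlantedEffect(**e) for e in d["effects"]],
            links=list(d["links"]),
            prognostic=[(g, float(c)) for g, c in d["prognostic"]],
            proportion_coef=float(d.get("proportion_coef", 0.0)),
        )


# ---------------------------------------------------------------------------
# small shared helpers

def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Van der Waerden scores of a vector, standardized to unit sample sd."""
    ranks = stats.rankdata(values)
    z = stats.norm.ppf(ranks / (len(values) + 1))
    return _standardize(z)


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise InvalidArgumentError("cannot standardize a constant vector")
    return v / sd


def _orthogonalized_noise(rng: np.random.Generator, z: np.ndarray) -> np.ndarray:
    """A unit-sd noise vector empirically uncorrelated with ``z``."""
    eta = rng.standard_normal(len(z))
    eta = eta - eta.mean()
    eta = eta - (eta @ z) / (z @ z) * z
    return _standardize(eta)


def _spearman_mixing_weight(strength: float) -> float:
    # For bivariate normal latents, Spearman rho = (6/pi) asin(w/2);
    # inverting gives w such that the population Spearman equals `strength`.
    return 2.0 * np.sin(np.pi * strength / 6.0)


def _planted_row(rng: np.random.Generator, z: np.ndarray, direction: int,
                 strength: float) -> np.ndarray:
    w = _spearman_mixing_weight(strength)
    eta = _orthogonalized_noise(rng, z)
    return direction * (w * z + np.sqrt(max(0.0, 1.0 - w * w)) * eta)


# ---------------------------------------------------------------------------
# cohort

def solve_beta_params(low_fraction: float, concentration: float = 6.0) -> tuple[float, float]:
    """Beta(a, b) with a + b = concentration and P(X < 0.5) = low_fraction."""
    if not 0.0 < low_fraction < 1.0:
        raise InvalidArgumentError("interior low_fraction required")
    lo, hi = 1e-6, concentration - 1e-6
    a = optimize.brentq(
        lambda a: stats.beta.cdf(0.5, a, concentration - a) - low_fraction, lo, hi
    )
    return a, concentration - a


def generate_cohort(n_samples: int, low_fraction: float, seed: int,
                    concentration: float = 6.0, cutoff: float = 0.5,
                    sample_prefix: str = "S") -> pd.DataFrame:
    """Sample a cohort of epithelial proportions skewed to match ``low_fraction``.

    Returns a DataFrame with sample_id, proportion, group ('high' iff
    proportion >= cutoff).
    """
    if n_samples < 2:
        raise InvalidArgumentError(f"n_samples must be >= 2, got {n_samples}")
    if not 0.0 <= low_fraction <= 1.0:
        raise InvalidArgumentError("low_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if low_fraction == 0.0:
        props = rng.uniform(cutoff, 1.0, n_samples)
    elif low_fraction == 1.0:
        props = rng.uniform(0.0, cutoff, n_samples)
    else:
        a, b = solve_beta_params(low_fraction, concentration)
        props = rng.beta(a, b, n_samples)
    width = max(3, len(str(n_samples)))
    sample_ids = [f"{sample_prefix}{i:0{width}d}" for i in range(1, n_samples + 1)]
    return pd.DataFrame({
        "sample_id": sample_ids,
        "proportion": props,
        "group": np.where(props >= cutoff, "high", "low"),
    })


# ---------------------------------------------------------------------------
# peak atlas and gene annotation

def generate_peak_atlas(genome: GenomeSpec = DEFAULT_GENOME, n_peaks: int = 1000,
                        width: int = 501, seed: int = 0) -> pd.DataFrame:
    """Uniform random non-overlapping peaks of fixed width; summit at midpoint."""
    if n_peaks < 1 or width < 1:
        raise InvalidArgumentError("n_peaks and width must be >= 1")
    lengths = np.array([c[1] for c in genome.chromosomes], dtype=float)
    # largest-remainder allocation proportional to chromosome length
    quota = n_peaks * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n_peaks - counts.sum()]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for (name, length), k in zip(genome.chromosomes, counts):
        if k == 0:
            continue
        slack = length - k * width
        if slack < 0:
            raise InvalidArgumentError(
                f"{k} peaks of width {width} do not fit on {name} (length {length})")
        # spacing trick: k sorted uniform points in the slack, shifted apart
        gaps = np.sort(rng.integers(0, slack + 1, size=k))
        starts = gaps + np.arange(k) * width
        for s in starts:
            idx += 1
            rows.append((f"peak_{idx:06d}", name, int(s), int(s + width), int(s + width // 2)))
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "summit"])


def generate_gene_annotation(genome: GenomeSpec = DEFAULT_GENOME, n_genes: int = 100,
                             seed: int = 0) -> pd.DataFrame:
    """Random TSS positions and strands across the genome."""
    if n_genes < 1:
        raise InvalidArgumentError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([c[1] for c in genome.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n_genes, p=lengths / lengths.sum())
    rows = []
    for i, ci in enumerate(chrom_idx, start=1):
        name, length = genome.chromosomes[ci]
        tss = int(rng.integers(2000, length - 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene_{i:05d}", name, tss, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


# ---------------------------------------------------------------------------
# matrices

def generate_accessibility(peaks: pd.DataFrame, cohort: pd.DataFrame,
                           effects: list[PlantedEffect], noise_sd: float = 1.0,
                           seed: int = 0, cn: pd.DataFrame | None = None,
                           cn_noise_sd: float = 0.2) -> pd.DataFrame:
    """Peak x sample accessibility with planted monotone phenotype coupling.

    Planted rows mix the phenotype's normal scores with empirically
    orthogonalized noise, the mixing weight chosen so the Spearman correlation
    with the proportion is ``direction * strength`` (exact at strength 1, up to
    rank-discretization error otherwise, at every noise_sd). Unplanted rows are
    pure noise of scale ``noise_sd``; planted rows are scaled to match. Rows of
    copy-number-driven effects instead track the matching row of ``cn``. All
    rows are shifted to be non-negative (a rank-preserving map).
    """
    if noise_sd <= 0:
        raise InvalidArgumentError("noise_sd must be > 0")
    known = set(peaks["peak_id"])
    for e in effects:
        if e.peak_id not in known:
            raise InvalidArgumentError(f"unknown peak_id in effects: {e.peak_id}")
        if e.cn_driven and (cn is None or e.peak_id not in cn.index):
            raise InvalidArgumentError(f"cn_driven effect {e.peak_id} has no copy-number row")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    z = _normal_scores(cohort["proportion"].to_numpy())
    values = noise_sd * rng.standard_normal((len(peaks), n))
    row_of = {pid: i for i, pid in enumerate(peaks["peak_id"])}
    for e in effects:
        i = row_of[e.peak_id]
        if e.cn_driven:
            base = _standardize(cn.loc[e.peak_id].to_numpy(dtype=float))
            values[i] = base + cn_noise_sd * rng.standard_normal(n)
        else:
            values[i] = noise_sd * _planted_row(rng, z, e.direction, e.strength)
    values -= values.min(axis=1, keepdims=True)
    return pd.DataFrame(values, index=pd.Index(peaks["peak_id"], name="peak_id"),
                        columns=cohort["sample_id"].tolist())


def generate_copy_number(peaks: pd.DataFrame, cohort: pd.DataFrame,
                         cn_driven_ids: list[str], seed: int = 0,
                         cn_strength: float = 0.8) -> pd.DataFrame:
    """Copy-number matrix over peaks; driven rows carry a phenotype-coupled signal.

    Non-driven rows sit near the diploid baseline. Driven rows are a latent
    amplification signal that itself correlates with the proportion, so that a
    driven peak can pass the phenotype screen yet be explained by copy number.
    """
    known = set(peaks["peak_id"])
    unknown = [pid for pid in cn_driven_ids if pid not in known]
    if unknown:
        raise InvalidArgumentError(f"unknown peak ids: {unknown}")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    z = _normal_scores(cohort["proportion"].to_numpy())
    values = 2.0 + 0.05 * rng.standard_normal((len(peaks), n))
    row_of = {pid: i for i, pid in enumerate(peaks["peak_id"])}
    for pid in cn_driven_ids:
        values[row_of[pid]] = 2.0 + _planted_row(rng, z, +1, cn_strength)
    return pd.DataFrame(values, index=pd.Index(peaks["peak_id"], name="peak_id"),
                        columns=cohort["sample_id"].tolist())


def generate_expression(genes: pd.DataFrame, cohort: pd.DataFrame,
                        truth: SyntheticTruth, seed: int = 0,
                        acc: pd.DataFrame | None = None,
                        cn: pd.DataFrame | None = None,
                        coupling: float = 0.9, noise_sd: float = 1.0,
                        cn_noise_sd: float = 0.2) -> pd.DataFrame:
    """Gene x sample expression; linked genes track their peak's accessibility.

    ``coupling`` is the empirical Pearson correlation between a linked gene's
    expression and the normal scores of its peak's accessibility (exactly 1 at
    coupling=1). Genes linked through a copy-number-driven peak track the
    copy-number row instead. Unlinked genes are independent noise.
    """
    if not 0.0 <= coupling <= 1.0:
        raise InvalidArgumentError("coupling must be in [0, 1]")
    known = set(genes["gene_id"])
    for link in truth.links:
        if link["gene_id"] not in known:
            raise InvalidArgumentError(f"linked gene not in annotation: {link['gene_id']}")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    values = noise_sd * rng.standard_normal((len(genes), n))
    row_of = {gid: i for i, gid in enumerate(genes["gene_id"])}
    for link in truth.links:
        gi = row_of[link["gene_id"]]
        if link.get("cn_driven") and cn is not None and link["peak_id"] in cn.index:
            base = _standardize(cn.loc[link["peak_id"]].to_numpy(dtype=float))
            values[gi] = base + cn_noise_sd * rng.standard_normal(n)
            continue
        if acc is None or link["peak_id"] not in acc.index:
            raise InvalidArgumentError(
                f"link references peak {link['peak_id']} absent from accessibility")
        base = _normal_scores(acc.loc[link["peak_id"]].to_numpy(dtype=float))
        if coupling == 1.0:
            values[gi] = base
        else:
            eta = _orthogonalized_noise(rng, base)
            values[gi] = coupling * base + np.sqrt(1.0 - coupling ** 2) * eta
    values -= values.min(axis=1, keepdims=True)
    return pd.DataFrame(values, index=pd.Index(genes["gene_id"], name="gene_id"),
                        columns=cohort["sample_id"].tolist())


# ---------------------------------------------------------------------------
# survival

def generate_survival(cohort: pd.DataFrame, expr: pd.DataFrame,
                      prognostic: list[tuple[str, float]], censor_rate: float,
                      seed: int = 0, baseline_hazard: float = 1.0 / 1500.0,
                      proportion_coef: float = 0.0) -> pd.DataFrame:
    """Exponential proportional-hazards survival times with independent censoring.

    The linear predictor is the sum of coefficient x standardized expression
    over the prognostic genes, plus ``proportion_coef`` x standardized
    proportion. Censoring times are exponential with the rate tuned so the
    expected censored fraction equals ``censor_rate``.
    """
    if len(cohort) == 0:
        raise InvalidArgumentError("empty cohort")
    if not 0.0 <= censor_rate < 1.0:
        raise InvalidArgumentError("censor_rate must be in [0, 1)")
    missing = [g for g, _ in prognostic if g not in expr.index]
    if missing:
        raise InvalidArgumentError(f"prognostic genes absent from expression: {missing}")
    rng = np.random.default_rng(seed)
    samples = cohort["sample_id"].tolist()
    lp = np.zeros(len(samples))
    for gene, coef in prognostic:
        lp += coef * _standardize(expr.loc[gene, samples].to_numpy(dtype=float))
    if proportion_coef != 0.0:
        lp += proportion_coef * _standardize(cohort["proportion"].to_numpy())
    hazard = baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate == 0.0:
        time, event = event_time, np.ones(len(samples), dtype=int)
    else:
        # P(C < T) for exponentials with rates rc, h is rc/(rc+h); solve the mean
        def censored_fraction(log_rc):
            rc = np.exp(log_rc)
            return np.mean(rc / (rc + hazard)) - censor_rate

        log_rc = optimize.brentq(censored_fraction, np.log(baseline_hazard) - 20,
                                 np.log(baseline_hazard) + 20)
        censor_time = rng.exponential(np.exp(-log_rc), size=len(samples))
        event = (event_time <= censor_time).astype(int)
        time = np.minimum(event_time, censor_time)
    return pd.DataFrame({
        "sample_id": samples,
        "time_days": np.maximum(time, 1e-3),
        "event": event,
    })


# ---------------------------------------------------------------------------
# masks

def generate_tissue_mask(height: int, width: int, target_proportion: float,
                         seed: int = 0) -> np.ndarray:
    """A label mask whose epithelial/(epi+stromal) pixel ratio hits the target.

    A smoothed random field is thresholded at the exact pixel quantile, giving
    spatially coherent regions with an exact epithelial count. A background
    margin is added when the mask is large enough.
    """
    if height <= 0 or width <= 0:
        raise InvalidArgumentError("mask dimensions must be positive")
    if not 0.0 <= target_proportion <= 1.0:
        raise InvalidArgumentError("target proportion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    margin = min(height, width) // 10 if min(height, width) >= 10 else 0
    mask = np.full((height, width), MASK_BACKGROUND, dtype=np.uint8)
    interior = np.s_[margin:height - margin or None, margin:width - margin or None]
    tissue_shape = mask[interior].shape
    n_tissue = tissue_shape[0] * tissue_shape[1]
    if n_tissue == 0:
        raise InvalidArgumentError("mask has no tissue area")
    fld = ndimage.gaussian_filter(rng.standard_normal(tissue_shape),
                                  sigma=max(1.0, min(tissue_shape) / 8.0))
    n_epi = int(round(target_proportion * n_tissue))
    order = np.argsort(fld, axis=None, kind="stable")
    labels = np.full(n_tissue, MASK_STROMAL, dtype=np.uint8)
    labels[order[:n_epi]] = MASK_EPITHELIAL
    mask[interior] = labels.reshape(tissue_shape)
    return mask


# ---------------------------------------------------------------------------
# coordinated bundle

@dataclass
class SyntheticBundle:
    genome: GenomeSpec
    cohort: pd.DataFrame
    peaks: pd.DataFrame
    genes: pd.DataFrame
    accessibility: pd.DataFrame
    expression: pd.DataFrame
    copy_number: pd.DataFrame | None
    survival: pd.DataFrame
    truth: SyntheticTruth
    # present when the survival cohort is distinct from the screen cohort
    survival_cohort: pd.DataFrame | None = None
    survival_expression: pd.DataFrame | None = None


def simulate_bundle(seed: int = 0, *, n_samples: int = 54, low_fraction: float = 47 / 54,
                    n_peaks: int = 400, n_genes: int = 80,
                    n_promoter_links: int = 5, n_distal_links: int = 3,
                    n_cn_links: int = 1, n_extra_effects: int = 12,
                    effect_strength: float = 0.85, coupling: float = 0.9,
                    noise_sd: float = 1.0, distal_offset: int = 50_000,
                    n_prognostic: int = 4, hazard_coef: float = 0.8,
                    proportion_coef: float = 0.5, censor_rate: float = 0.5,
                    n_survival_samples: int | None = None,
                    genome: GenomeSpec = DEFAULT_GENOME,
                    peak_width: int = 501) -> SyntheticBundle:
    """Build a coherent synthetic study: cohort, atlas, matrices, survival, truth.

    Planted structure: ``n_promoter_links`` genes whose promoter window holds a
    planted peak's summit, ``n_distal_links`` genes at ``distal_offset`` bp from
    a planted peak with coupled expression, ``n_cn_links`` copy-number-driven
    distal pairs, and ``n_extra_effects`` additional phenotype-coupled peaks
    with no gene. Prognostic genes are drawn from the linked genes.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(8)
    rng = np.random.default_rng(seeds[0])

    cohort = generate_cohort(n_samples, low_fraction, int(seeds[1]))
    peaks = generate_peak_atlas(genome, n_peaks, width=peak_width, seed=int(seeds[2]))
    genes = generate_gene_annotation(genome, n_genes, seed=int(seeds[3]))

    n_planted = n_promoter_links + n_distal_links + n_cn_links + n_extra_effects
    if n_planted > n_peaks:
        raise InvalidArgumentError("more planted effects than peaks")
    chosen = rng.choice(len(peaks), size=n_planted, replace=False)
    directions = np.where(rng.random(n_planted) < 0.5, 1, -1)

    chrom_len = dict(genome.chromosomes)
    effects: list[PlantedEffect] = []
    links: list[dict] = []
    gene_rows = genes.copy()
    cursor = 0

    def relocate_gene(gi: int, chrom: str, tss: int, strand: str) -> None:
        gene_rows.loc[gene_rows.index[gi], ["chrom", "tss", "strand"]] = [chrom, tss, strand]

    # promoter-linked genes: TSS 500 bp downstream of the summit on '+'
    for j in range(n_promoter_links):
        pk = peaks.iloc[chosen[cursor]]
        gid = gene_rows.iloc[j]["gene_id"]
        relocate_gene(j, pk["chrom"], int(pk["summit"]) + 1 + 500, "+")
        effects.append(PlantedEffect(pk["peak_id"], int(directions[cursor]),
                                     effect_strength, linked_gene=gid))
        links.append({"peak_id": pk["peak_id"], "gene_id": gid,
                      "kind": "promoter", "cn_driven": False})
        cursor += 1

    # distal-linked genes: TSS `distal_offset` bp away, outside promoter reach
    for j in range(n_distal_links + n_cn_links):
        pk = peaks.iloc[chosen[cursor]]
        gi = n_promoter_links + j
        gid = gene_rows.iloc[gi]["gene_id"]
        tss = int(pk["summit"]) + 1 + distal_offset
        if tss >= chrom_len[pk["chrom"]]:
            tss = int(pk["summit"]) + 1 - distal_offset
        relocate_gene(gi, pk["chrom"], tss, "+")
        cn_driven = j >= n_distal_links
        effects.append(PlantedEffect(pk["peak_id"], int(directions[cursor]),
                                     effect_strength, linked_gene=gid, cn_driven=cn_driven))
        links.append({"peak_id": pk["peak_id"], "gene_id": gid,
                      "kind": "distal", "cn_driven": cn_driven})
        cursor += 1

    for _ in range(n_extra_effects):
        pk = peaks.iloc[chosen[cursor]]
        effects.append(PlantedEffect(pk["peak_id"], int(directions[cursor]), effect_strength))
        cursor += 1

    cn_ids = [e.peak_id for e in effects if e.cn_driven]
    copy_number = generate_copy_number(peaks, cohort, cn_ids, seed=int(seeds[4]))
    truth = SyntheticTruth(effects=effects, links=links)
    accessibility = generate_accessibility(peaks, cohort, effects, noise_sd=noise_sd,
                                           seed=int(seeds[5]), cn=copy_number)
    expression = generate_expression(gene_rows, cohort, truth, seed=int(seeds[6]),
                                     acc=accessibility, cn=copy_number, coupling=coupling)

    linkable = [l["gene_id"] for l in links if not l["cn_driven"]]
    prognostic = [(g, hazard_coef) for g in linkable[:n_prognostic]]
    truth.prognostic = prognostic
    truth.proportion_coef = proportion_coef

    surv_cohort = surv_expr = None
    if n_survival_samples and n_survival_samples != n_samples:
        # a distinct follow-up cohort with its own ids, like the expression
        # cohort used for the prognosis stage
        surv_cohort = generate_cohort(n_survival_samples, low_fraction,
                                      int(seeds[7]) + 1, sample_prefix="T")
        surv_expr = generate_expression(gene_rows, surv_cohort, truth, seed=int(seeds[7]) + 2,
                                        acc=generate_accessibility(
                                            peaks, surv_cohort, effects, noise_sd=noise_sd,
                                            seed=int(seeds[7]) + 3,
                                            cn=generate_copy_number(
                                                peaks, surv_cohort, cn_ids,
                                                seed=int(seeds[7]) + 4)),
                                        coupling=coupling)
        survival = generate_survival(surv_cohort, surv_expr, prognostic, censor_rate,
                                     seed=int(seeds[7]), proportion_coef=proportion_coef)
    else:
        survival = generate_survival(cohort, expression, prognostic, censor_rate,
                                     seed=int(seeds[7]), proportion_coef=proportion_coef)

    return SyntheticBundle(genome=genome, cohort=cohort, peaks=peaks, genes=gene_rows,
                           accessibility=accessibility, expression=expression,
                           copy_number=copy_number, survival=survival, truth=truth,
                           survival_cohort=surv_cohort, survival_expression=surv_expr)
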