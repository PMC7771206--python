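"""Over-representation analysis of target genes against gene-set collections."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultError, InvalidArgumentError
from .screen import bh_fdr

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        if not self.universe:
            raise InvalidArgumentError("empty universe")
        restricted = {}
        for name, genes in self.sets.items():
            inside = genes & self.universe
            if inside:
                restricted[name] = inside
            else:
                log.warning("gene set %s has no genes in the universe; dropped", name)
        self.sets = restricted


def hypergeometric_enrich(hits: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each set's overlap with the hit list.

    p = P(overlap >= observed) drawing |hits| genes from the universe;
    BH q-values across sets; results sorted by p then set name.
    """
    outside = hits - collection.universe
    if outside:
        log.warning("%d hit genes outside the universe dropped", len(outside))
    hits = hits & collection.universe
    if not hits:
        raise EmptyResultError("no hit genes inside the universe")
    M, N = len(collection.universe), len(hits)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        K = len(genes)
        k = len(genes & hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append((name, K, k, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table["neg_log10_p"] = -np.log10(table["p_value"])
    return table.sort_values(["p_value", "set_name"]).reset_index(drop=True)


def enrich_by_sign(targets: pd.DataFrame, collection: GeneSetCollection) -> pd.DataFrame:
    """Run the over-representation test separately per target-gene sign group."""
    frames = []
    for sign in ("positive", "negative"):
        hits = set(targets.loc[targets["sign"] == sign, "gene_id"])
        if not hits:
            continue
        try:
            table = hypergeometric_enrich(hits, collection)
        except EmptyResultError:
            continue
        table.insert(0, "group", sign)
        frames.append(table)
    if not frames:
        return pd.DataFrame(columns=["group", "set_name", "set_size", "overlap",
                                     "p_value", "fdr", "neg_log10_p"])
    return pd.concat(frames, ignore_index=True)
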