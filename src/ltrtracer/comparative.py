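"""Genome-size arithmetic and cross-species correlation statistics.

Covers the comparative layer of the pipeline: picogram-to-megabase
conversion (1 pg = 978 Mb), sequencing coverage C = LN/G against the
haploid (1C = 2C/2) genome size, ordinary Pearson correlation, and
phylogenetically independent contrasts (Felsenstein's algorithm) with
drop-tip pruning of the species tree.

The packaged species table carries, per species: abbreviation, accession,
post-processing read-pair count, flow-cytometry 2C genome size (pg, with
SE), the printed genome coverage, and the graph-clustering repetitive
fraction (%, with SE).  The packaged species tree is the study topology
(hybrid-origin H. anomalus excluded) with unit branch lengths; true
branch lengths were not published, so PIC results on this tree depend on
that convention and user-supplied lengths can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

PG_PER_MB = 978.0  # 1 pg = 978 Mb
DEFAULT_READ_LENGTH = 100


def _data_path(name: str):
    return resources.files("ltrtracer.data").joinpath(name)


def load_species_table(path=None) -> pd.DataFrame:
    """The study species table (packaged copy by default)."""
    if path is None:
        with resources.as_file(_data_path("species_table.tsv")) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def load_study_tree(path=None) -> dendropy.Tree:
    """The study species-tree topology (unit branch lengths) as dendropy."""
    if path is None:
        text = _data_path("species_tree.nwk").read_text()
        return dendropy.Tree.get(data=text, schema="newick")
    return dendropy.Tree.get(path=str(path), schema="newick")


def pg_to_mb(pg: float) -> float:
    """Convert a DNA mass in picograms to megabases (1 pg = 978 Mb)."""
    if pg < 0:
        raise ValueError("pg must be >= 0")
    return pg * PG_PER_MB


def genome_coverage(
    read_pairs: int, read_length: int = DEFAULT_READ_LENGTH, c2_pg: float = None
) -> float:
    """Sequencing coverage C = LN/G with N counting both mates of a pair.

    G is the haploid genome length, 1C = 2C/2, converted at 978 Mb/pg.
    """
    if read_pairs <= 0 or read_length <= 0 or c2_pg is None or c2_pg <= 0:
        raise ValueError("read_pairs, read_length and c2_pg must be > 0")
    genome_bases = pg_to_mb(c2_pg / 2.0) * 1e6
    return read_length * (2 * read_pairs) / genome_bases


def round2(x: float) -> float:
    """Report helper: two decimals, round-half-even (as printed coverages)."""
    return float(round(x, 2))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r with the two-sided t-test p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def drop_tips(tree: dendropy.Tree, remove: Sequence[str]) -> dendropy.Tree:
    """Prune named tips, suppressing unifurcations (branch lengths summed).

    Root-to-tip path lengths of the surviving tips are preserved.  The
    input tree is not modified; unknown labels raise.
    """
    pruned = tree.clone(depth=1)
    labels = {t.label for t in pruned.taxon_namespace}
    for name in remove:
        if name not in labels:
            raise ValueError(f"tip {name!r} not present in tree")
    if remove:
        pruned.prune_taxa_with_labels(list(remove), suppress_unifurcations=True)
    return pruned


@dataclass
class ContrastSet:
    """Standardized independent contrasts for one trait (n-1 per n tips)."""

    contrasts: np.ndarray
    #: expected variance (sum of adjusted branch lengths) per contrast
    variances: np.ndarray

    def __len__(self) -> int:
        return len(self.contrasts)


def pic(tree: dendropy.Tree, trait: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    Post-order over a fully bifurcating tree: at each internal node the
    contrast is the difference of the two daughter values standardized by
    the square root of the summed (adjusted) branch lengths; the node is
    assigned the branch-length-weighted average of its daughters and its
    parent branch is extended by the product-over-sum correction.
    Polytomies and missing tip values raise.
    """
    contrasts = []
    variances = []
    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label not in trait:
                raise ValueError(f"tip {label!r} has no trait value")
            values[id(node)] = float(trait[label])
            edge = node.edge.length
            if edge is None or edge <= 0:
                raise ValueError(f"tip {label!r} lacks a positive branch length")
            lengths[id(node)] = float(edge)
        else:
            children = node.child_nodes()
            if len(children) != 2:
                raise ValueError(
                    f"tree is not fully bifurcating (node with {len(children)} children)"
                )
            c1, c2 = children
            v1, v2 = values[id(c1)], values[id(c2)]
            b1, b2 = lengths[id(c1)], lengths[id(c2)]
            var = b1 + b2
            contrasts.append((v1 - v2) / math.sqrt(var))
            variances.append(var)
            values[id(node)] = (v1 / b1 + v2 / b2) / (1.0 / b1 + 1.0 / b2)
            edge = node.edge.length if node.parent_node is not None else 0.0
            if node.parent_node is not None and (edge is None or edge <= 0):
                raise ValueError("internal branch without positive length")
            lengths[id(node)] = float(edge or 0.0) + b1 * b2 / (b1 + b2)
    return ContrastSet(
        contrasts=np.array(contrasts), variances=np.array(variances)
    )


def pic_correlation(
    tree: dendropy.Tree, x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[float, float]:
    """Correlation of two contrast sets, through the origin.

    r = sum(uv) / sqrt(sum(u^2) sum(v^2)); the two-sided p comes from the
    t transform with (number of contrasts - 1) degrees of freedom.
    """
    u = pic(tree, x).contrasts
    v = pic(tree, y).contrasts
    su = float(np.dot(u, u))
    sv = float(np.dot(v, v))
    if su == 0 or sv == 0:
        raise ValueError("zero variance in contrasts")
    r = float(np.dot(u, v) / math.sqrt(su * sv))
    df = len(u) - 1
    if df < 1:
        raise ValueError("need at least 2 contrasts")
    r_clamped = max(-1.0, min(1.0, r))
    if abs(r_clamped) == 1.0:
        p = 0.0
    else:
        t = r_clamped * math.sqrt(df / (1.0 - r_clamped * r_clamped))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def study_correlations(
    table: Optional[pd.DataFrame] = None,
    tree: Optional[dendropy.Tree] = None,
    exclude_from_pic: Sequence[str] = ("ANO",),
) -> dict:
    """Genome size vs repetitive fraction: Pearson and PIC correlations.

    Uses all species for the ordinary Pearson correlation and prunes the
    named tips (by abbreviation; default the hybrid-origin H. anomalus)
    for the phylogenetically adjusted analysis.
    """
    table = table if table is not None else load_species_table()
    tree = tree if tree is not None else load_study_tree()
    r, p = pearson_correlation(
        table["c2_pg"].to_numpy(), table["repetitive_fraction_pct"].to_numpy()
    )
    tip_labels = {t.label for t in tree.taxon_namespace}
    pic_table = table[table["abbreviation"].isin(tip_labels)]
    x = dict(zip(pic_table["abbreviation"], pic_table["c2_pg"]))
    y = dict(zip(pic_table["abbreviation"], pic_table["repetitive_fraction_pct"]))
    pruned = drop_tips(tree, [t for t in exclude_from_pic if t in tip_labels])
    keep = {t.taxon.label for t in pruned.leaf_node_iter()}
    x = {k: v for k, v in x.items() if k in keep}
    y = {k: v for k, v in y.items() if k in keep}
    pic_r, pic_p = pic_correlation(pruned, x, y)
    return {
        "pearson_r": r,
        "pearson_p": p,
        "pearson_n": int(len(table)),
        "pic_r": pic_r,
        "pic_p": pic_p,
        "pic_n_tips": len(keep),
    }
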