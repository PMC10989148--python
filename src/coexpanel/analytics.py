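"""Downstream panel analytics.

Keyword-based functional gene extraction, per-panel pathway enrichment,
hub/signaling panel designation, weighted correlation topology networks with
modularity classes and landmark genes, and the absorbance-based reactive
oxygen species (ROS) production-rate utility.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .panels import PanelAssignment

logger = logging.getLogger(__name__)

PD_KEYWORDS = ("nitrate", "nitrite")

ENRICHMENT_P_MAX = 0.01
ENRICHMENT_FC_LOW = 0.5
ENRICHMENT_FC_HIGH = 2.0
ENRICHMENT_MIN_FPKM = 10.0

CORRELATION_R_MIN = 0.9
CORRELATION_P_MAX = 0.05
N_LANDMARKS = 3


def extract_function_genes(
    annotations: pd.DataFrame,
    keywords: Sequence[str],
    expression: pd.DataFrame,
    min_mean_expression: float = 1.0,
) -> list[str]:
    """Genes whose description contains any keyword (case-insensitive
    substring) and whose mean FPKM over the given samples is >= the cutoff.

    To pool several condition datasets, call once per dataset and take the
    union of the results ("merge the eligible genes").
    """
    if not keywords:
        raise ParameterError("keyword list must not be empty")
    lowered = [k.lower() for k in keywords]
    desc = annotations["description"].astype(str).str.lower()
    matched = desc[[any(k in d for k in lowered) for d in desc]].index
    means = expression.mean(axis=1)
    kept = [
        g for g in matched if g in means.index and means[g] >= min_mean_expression
    ]
    logger.info(
        "keyword extraction: %d matched, %d above %.3g FPKM",
        len(matched),
        len(kept),
        min_mean_expression,
    )
    return sorted(kept)


def enrich_pathways(
    panel_genes: Iterable[str],
    annotations: pd.DataFrame,
    expression: pd.DataFrame,
    light_samples: Sequence[str],
    dark_samples: Sequence[str],
    *,
    p_max: float = ENRICHMENT_P_MAX,
    fc_low: float = ENRICHMENT_FC_LOW,
    fc_high: float = ENRICHMENT_FC_HIGH,
    min_fpkm: float = ENRICHMENT_MIN_FPKM,
    use_ttest: bool = False,
) -> pd.DataFrame:
    """Per-pathway expression summary within a panel, light vs dark control.

    For each pathway with members in the panel: mean light-condition FPKM
    (mean over member-gene means), fold change against the dark means, and a
    p-value from a paired-by-gene Wilcoxon signed-rank test of member-gene
    light vs dark means (``use_ttest=True`` switches to a paired t-test).
    A pathway passes the filter when p < ``p_max``, the fold change is
    outside [``fc_low``, ``fc_high``], and mean light expression is at least
    ``min_fpkm``. Pathways with < 3 member genes get no p-value and never
    pass.
    """
    panel_genes = [g for g in panel_genes if g in expression.index]
    light = expression.loc[panel_genes, list(light_samples)].mean(axis=1)
    dark = expression.loc[panel_genes, list(dark_samples)].mean(axis=1)

    by_pathway: dict[str, list[str]] = {}
    for g in panel_genes:
        if g in annotations.index:
            for p in annotations.loc[g, "pathways"]:
                by_pathway.setdefault(p, []).append(g)
    if not by_pathway:
        raise ValidationError("no pathway annotations among the panel genes")

    rows = []
    brite = annotations["brite"] if "brite" in annotations.columns else None
    for pathway, members in sorted(by_pathway.items()):
        ml, md = float(light[members].mean()), float(dark[members].mean())
        fc = ml / md if md > 0 else np.inf if ml > 0 else np.nan
        if len(members) < 3:
            pval = np.nan
        else:
            diffs = light[members].to_numpy() - dark[members].to_numpy()
            if use_ttest:
                pval = float(stats.ttest_rel(light[members], dark[members]).pvalue)
            elif np.allclose(diffs, 0.0):
                pval = 1.0
            else:
                pval = float(
                    stats.wilcoxon(diffs, zero_method="wilcox", method="auto").pvalue
                )
        passes = (
            not np.isnan(pval)
            and pval < p_max
            and (fc < fc_low or fc > fc_high)
            and ml >= min_fpkm
        )
        rows.append(
            {
                "pathway": pathway,
                "brite": (
                    str(brite[members[0]])
                    if brite is not None and members[0] in brite.index
                    else ""
                ),
                "n_genes": len(members),
                "mean_expression": ml,
                "fold_change": fc,
                "p_value": pval,
                "passes_filter": bool(passes),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PanelDesignation:
    """Hub gene panel / signaling gene panel designation for one dataset."""

    hgp: int | None
    sgp: int | None
    conflict: bool
    stats: pd.DataFrame = field(repr=False)


def _plurality_cluster(
    assignment: PanelAssignment, genes: Sequence[str], expression: pd.DataFrame
) -> int | None:
    present = [g for g in genes if g in set(assignment.node_ids)]
    if not present:
        return None
    counts = assignment.as_series().loc[present].value_counts()
    top = counts[counts == counts.max()].index.tolist()
    if len(top) > 1:
        # tie on membership: break toward the higher summed expression
        sums = {
            int(c): float(
                expression.loc[
                    [g for g in present if assignment.label_of(g) == c]
                ].to_numpy().sum()
            )
            for c in top
        }
        warnings.warn(
            f"plurality tie between clusters {sorted(sums)}; "
            "resolved by summed expression",
            stacklevel=3,
        )
        return max(sorted(sums), key=lambda c: sums[c])
    return int(top[0])


def designate_panels(
    assignment: PanelAssignment,
    pd_genes: Sequence[str],
    phototransduction_genes: Sequence[str],
    expression: pd.DataFrame,
    degs: pd.DataFrame | None = None,
) -> PanelDesignation:
    """Designate the hub gene panel (plurality of the functional/PD genes) and
    the signaling gene panel (plurality of the phototransduction genes).

    Reports each designated panel's mean FPKM and, when a DEG table is given,
    its mean |log2 fold change|. A shared designation raises a warning and is
    flagged as a conflict.
    """
    hgp = _plurality_cluster(assignment, pd_genes, expression)
    sgp = _plurality_cluster(assignment, phototransduction_genes, expression)
    if hgp is None:
        warnings.warn("empty PD gene set; HGP designation skipped", stacklevel=2)
    if sgp is None:
        warnings.warn(
            "empty phototransduction gene set; SGP designation skipped", stacklevel=2
        )
    conflict = hgp is not None and hgp == sgp
    if conflict:
        warnings.warn(
            f"HGP and SGP designate the same cluster {hgp}", stacklevel=2
        )
    series = assignment.as_series()
    lfc = (
        degs.set_index("gene_id")["log2_fold_change"]
        if degs is not None
        else None
    )
    rows = []
    for role, cluster in (("HGP", hgp), ("SGP", sgp)):
        if cluster is None:
            continue
        members = series.index[series == cluster]
        row = {
            "role": role,
            "cluster": cluster,
            "n_genes": len(members),
            "mean_expression": float(expression.loc[members].to_numpy().mean()),
        }
        if lfc is not None:
            row["mean_abs_log2fc"] = float(lfc.reindex(members).abs().mean())
        rows.append(row)
    return PanelDesignation(hgp, sgp, conflict, pd.DataFrame(rows))


def correlation_pvalue(r: np.ndarray, m: int) -> np.ndarray:
    """Two-sided p for Pearson r with m samples via the t transform."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((m - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def build_topology_network(
    panel_expression: pd.DataFrame,
    r_min: float = CORRELATION_R_MIN,
    p_max: float = CORRELATION_P_MAX,
    absolute: bool = False,
) -> nx.Graph:
    """All-pairs Pearson correlation graph with edge filtering.

    Edges keep pairs with ``r >= r_min`` (signed rule; ``absolute=True``
    filters on ``|r|``) and correlation p-value ``<= p_max``; the edge weight
    is r. Zero-variance genes cannot be correlated and are dropped with a log
    entry. Every retained panel gene is a node, connected or not.
    """
    m = panel_expression.shape[1]
    if m < 3:
        raise ParameterError("correlation needs at least 3 samples per gene")
    if panel_expression.shape[0] < 2:
        raise ParameterError("panel needs at least 2 genes")
    values = panel_expression.to_numpy(float)
    variable = values.std(axis=1) > 0
    dropped = list(panel_expression.index[~variable])
    if dropped:
        logger.info("excluding %d zero-variance genes: %s", len(dropped), dropped[:5])
    genes = list(panel_expression.index[variable])
    g = nx.Graph()
    g.add_nodes_from(genes)
    if len(genes) >= 2:
        corr = np.corrcoef(values[variable])
        iu, ju = np.triu_indices(len(genes), k=1)
        r = corr[iu, ju]
        p = correlation_pvalue(r, m)
        keep = (np.abs(r) >= r_min if absolute else r >= r_min) & (p <= p_max)
        for i, j, rij in zip(iu[keep], ju[keep], r[keep]):
            g.add_edge(genes[i], genes[j], weight=float(rij))
    return g


def compute_topology_metrics(
    network: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> pd.DataFrame:
    """Node metrics + modularity classes for a correlation network.

    Modularity classes come from seeded Louvain on the edge weights.
    Eccentricity, closeness and harmonic closeness are computed within each
    connected component (harmonic closeness normalized by component size − 1);
    betweenness is unnormalized shortest-path betweenness on the unweighted
    graph; the clustering coefficient is the unweighted triangle density.
    """
    if network.number_of_nodes() == 0:
        raise ParameterError("empty network")
    if network.number_of_edges() == 0:
        warnings.warn("network has no edges; metrics are degenerate", stacklevel=2)
    communities = nx.community.louvain_communities(
        network, weight="weight", seed=seed, resolution=resolution
    )
    modularity_class = {}
    for cid, members in enumerate(communities):
        for node in members:
            modularity_class[node] = cid

    degree = dict(network.degree())
    wdegree = dict(network.degree(weight="weight"))
    betweenness = nx.betweenness_centrality(network, normalized=False)
    clustering = nx.clustering(network)

    ecc: dict = {}
    closeness: dict = {}
    harmonic: dict = {}
    for comp in nx.connected_components(network):
        sub = network.subgraph(sorted(comp))
        ecc.update(nx.eccentricity(sub))
        closeness.update(nx.closeness_centrality(sub))
        denom = max(len(comp) - 1, 1)
        for node in sub.nodes:
            # fixed summation order keeps the value bit-identical across runs
            lengths = nx.single_source_shortest_path_length(sub, node)
            harmonic[node] = (
                sum(1.0 / lengths[t] for t in sorted(lengths) if t != node) / denom
            )

    df = pd.DataFrame(
        {
            "gene_id": list(network.nodes),
            "degree": [degree[n] for n in network.nodes],
            "weighted_degree": [wdegree[n] for n in network.nodes],
            "modularity_class": [modularity_class[n] for n in network.nodes],
            "eccentricity": [ecc[n] for n in network.nodes],
            "closeness": [closeness[n] for n in network.nodes],
            "harmonic_closeness": [harmonic[n] for n in network.nodes],
            "betweenness": [betweenness[n] for n in network.nodes],
            "clustering_coefficient": [clustering[n] for n in network.nodes],
        }
    )
    return df.set_index("gene_id")


def landmark_genes(
    metrics: pd.DataFrame,
    expression: pd.DataFrame,
    light_samples: Sequence[str],
    n_landmarks: int = N_LANDMARKS,
) -> dict[int, list[str]]:
    """Top genes per modularity class by mean FPKM over light-exposed samples.

    Classes smaller than ``n_landmarks`` contribute all their members. Equal
    means are broken by gene id ascending (logged).
    """
    means = expression[list(light_samples)].mean(axis=1)
    out: dict[int, list[str]] = {}
    for cid, group in metrics.groupby("modularity_class"):
        ranked = sorted(group.index, key=lambda g: (-means.get(g, 0.0), g))
        chosen = ranked[:n_landmarks]
        if len(ranked) > n_landmarks:
            cutoff = means.get(ranked[n_landmarks - 1], 0.0)
            if np.isclose(means.get(ranked[n_landmarks], 0.0), cutoff):
                logger.info(
                    "class %s: tie at the landmark cutoff broken lexicographically",
                    cid,
                )
        out[int(cid)] = chosen
    return out


def export_network(
    network: nx.Graph, metrics: pd.DataFrame, path, fmt: str = "gexf"
) -> None:
    """Write the network with all node metrics attached (GEXF or GraphML)."""
    g = network.copy()
    for col in metrics.columns:
        nx.set_node_attributes(
            g, {n: _py(v) for n, v in metrics[col].items()}, name=col
        )
    if fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ParameterError(f"unknown network format {fmt!r}")


def _py(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def ros_production_rate(a_t, a_0, od600, min_abs: float = 0.85):
    """DPBF-consumption ROS production rate ``k = (1 − A_t/A_0)/OD600 × 10³``.

    Vectorized over ``a_t``; timepoints with insufficient substrate
    (absorbance ≤ ``min_abs``) are outside the kinetic regime and trigger a
    warning (the caller should pre-filter them).
    """
    a_t = np.asarray(a_t, dtype=float)
    if a_0 <= 0:
        raise ParameterError("initial absorbance must be positive")
    if np.any(np.asarray(od600) <= 0):
        raise ParameterError("OD600 must be positive")
    if np.any(a_t <= min_abs):
        warnings.warn(
            f"absorbance at or below {min_abs}: substrate may be depleted",
            stacklevel=2,
        )
    rate = (1.0 - a_t / a_0) / od600 * 1e3
    return float(rate) if rate.ndim == 0 else rate
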