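"""External validation of a fitted consensus network, and network anatomy.

*Replication*: the consensus edges and the tail model fitted on the model
sample are applied, unchanged, to an independent patient sample; a
significant covariate-adjusted correlation between predicted and observed
scores demonstrates that the network transfers. *Specificity*: the same
transfer to healthy controls is expected to be null — non-rejection is the
"pass", with the usual evidence-of-absence caveat.

*Anatomy*: a consensus mask is summarized as per-node degree (number of
incident consensus edges) and a K x K matrix of within- and
between-network connection counts keyed to the atlas networks, plus a
plot-ready edge list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Atlas, edge_index
from .cpm import EdgeMask, TailModel, fit_tail_model, network_strength, partial_correlation


@dataclass
class ValidationReport:
    """Transfer of one consensus network to one independent sample."""

    sample: str
    n: int
    r: float
    p: float
    df: int
    p_fdr: float | None = None
    covariates: list | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("need n >= 10 for a reported correlation")


def fit_consensus_model(edges_model: np.ndarray, behaviour_model,
                        consensus: EdgeMask, sign: int) -> TailModel:
    """Refit the tail model on the full model sample with consensus strengths.

    Deterministic transfer coefficients (rather than an average over fold
    models): strength under the consensus mask, OLS on all model subjects.
    """
    s = network_strength(edges_model, consensus, sign)
    return fit_tail_model(s, behaviour_model)


def external_validate(consensus: EdgeMask, model: TailModel,
                      edges_new: np.ndarray, behaviour_new,
                      covariates_new=None, *, sign: int,
                      sample: str = "validation",
                      provenance: str = "") -> ValidationReport:
    """Apply a consensus network + tail model to an independent sample.

    Per new subject: strength over the consensus edges of the requested
    sign, prediction ``slope * strength + intercept``, then the
    covariate-adjusted correlation between predictions and observed scores
    (df = m - 2 - k).
    """
    if consensus.n_edges == 0:
        raise ValueError("no consensus edges to transfer")
    y = np.asarray(behaviour_new, dtype=float).ravel()
    strengths = network_strength(edges_new, consensus, sign)
    preds = model.predict(strengths)
    r, p, df = partial_correlation(preds, y, covariates_new)
    return ValidationReport(sample=sample, n=len(y), r=r, p=p, df=df,
                            provenance=provenance)


@dataclass
class NetworkSummary:
    """Anatomy of a consensus network against an atlas.

    ``node_degree``: per-node count of incident selected edges (indexed by
    node_id). ``pair_counts``: K x K symmetric DataFrame of edge counts per
    unordered network pair (within-network counts on the diagonal; each
    undirected edge counted once). ``edge_list``: (node_i, node_j, sign),
    1-based, sorted.
    """

    node_degree: pd.Series
    pair_counts: pd.DataFrame
    edge_list: pd.DataFrame

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)


def summarize_network(mask: EdgeMask, atlas: Atlas) -> NetworkSummary:
    """Degree, network-pair counts, and edge list for a consensus mask."""
    if mask.n_nodes != atlas.n_nodes:
        raise ValueError("mask and atlas node counts differ")
    n = mask.n_nodes
    iu, ju = edge_index(n)
    sign = mask.values[iu, ju]
    keep = sign != 0
    ei, ej, es = iu[keep], ju[keep], sign[keep]

    degree = np.zeros(n, dtype=int)
    np.add.at(degree, ei, 1)
    np.add.at(degree, ej, 1)
    node_degree = pd.Series(degree, index=atlas.table["node_id"].to_numpy(),
                            name="degree")
    node_degree.index.name = "node_id"

    nets = atlas.networks
    net_of = atlas.node_networks
    kidx = {name: k for k, name in enumerate(nets)}
    counts = np.zeros((len(nets), len(nets)), dtype=int)
    for a, b in zip(ei, ej):
        ka, kb = kidx[net_of[a]], kidx[net_of[b]]
        lo, hi = min(ka, kb), max(ka, kb)
        counts[lo, hi] += 1
    counts = counts + np.triu(counts, 1).T  # symmetric, diagonal counted once
    pair_counts = pd.DataFrame(counts, index=nets, columns=nets)

    edge_list = pd.DataFrame({
        "node_i": ei + 1, "node_j": ej + 1, "sign": es.astype(int),
    }).sort_values(["node_i", "node_j"]).reset_index(drop=True)
    return NetworkSummary(node_degree=node_degree, pair_counts=pair_counts,
                          edge_list=edge_list)


def rank_nodes(summary: NetworkSummary, top_k: int = 10) -> pd.DataFrame:
    """Nodes ordered by degree (descending), ties broken by node_id ascending."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    t = summary.node_degree.reset_index()
    t = t.sort_values(["degree", "node_id"], ascending=[False, True])
    return t.head(top_k).reset_index(drop=True)
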