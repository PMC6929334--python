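"""End-to-end DNLC analysis on aligned inputs."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .dcselect import LfdrFit, associate_genes
from .io import ClinicalTable, align_inputs
from .lmi import compute_lmi, normal_score_transform
from .netweights import NeighborhoodWeights, network_weights


@dataclass
class DnlcResult:
    """Artifacts of one DNLC run."""

    association: pd.DataFrame
    lfdr_fit: LfdrFit
    untestable: pd.DataFrame
    lmi: pd.DataFrame
    weights: NeighborhoodWeights

    @property
    def dc_genes(self) -> list[str]:
        mask = self.association["is_dc"]
        return self.association.loc[mask, "gene_id"].tolist()

    def dc_signs(self) -> dict[str, int]:
        """+1/-1 per DC gene by the sign of its association statistic."""
        sel = self.association[self.association["is_dc"]]
        return {
            g: (1 if s > 0 else -1)
            for g, s in zip(sel["gene_id"], sel["statistic"])
        }


def run_dnlc(
    expr: pd.DataFrame,
    net: nx.Graph,
    clin: ClinicalTable,
    *,
    radius: int = 2,
    lfdr_threshold: float = 0.2,
    align: bool = True,
    **lfdr_kwargs,
) -> DnlcResult:
    """Run the full pipeline: align, normal-score, LMI, associate, lfdr.

    With ``align=True`` (default) expression/network/clinical inputs are
    first restricted to their common genes and samples.
    """
    if align:
        expr, net, clin = align_inputs(expr, net, clin)
    weights = network_weights(net, radius=radius, gene_order=list(expr.index))
    scores = normal_score_transform(expr)
    lmi = compute_lmi(scores, weights)
    table, fit, untestable = associate_genes(
        lmi, clin, isolated=weights.isolated, lfdr_threshold=lfdr_threshold, **lfdr_kwargs
    )
    return DnlcResult(
        association=table, lfdr_fit=fit, untestable=untestable, lmi=lmi, weights=weights
    )
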