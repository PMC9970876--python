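"""Tissue-of-action scoring: expression specificity x epigenetic evidence.

For each gene, specificity in a tissue is that tissue's share of the summed
median TPM; epigenetic evidence is the strongest promoter/enhancer mark
overlapping the lead instrument or a close LD proxy in a cell line mapped to
the tissue.  The two criteria are combined multiplicatively with configurable
evidence weights — a transparent stand-in for a sort on the two raw criteria,
which are always emitted alongside the combined score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import DegenerateInputError, ReferencePanel, ld_r2

DEFAULT_WEIGHTS = {"none": 1.0, "enhancer": 2.0, "promoter": 3.0, "both": 4.0}
_EVIDENCE_ORDER = {"none": 0, "enhancer": 1, "promoter": 2, "both": 3}


@dataclass(frozen=True)
class TissueScore:
    gene: str
    tissue: str
    specificity: float
    epi_evidence: str
    score: float
    log10_score: Optional[float]
    rank: int


def specificity(tpm_table: pd.DataFrame, gene: str) -> pd.Series:
    """Per-tissue fraction of the gene's total median TPM (sums to 1)."""
    sub = tpm_table[tpm_table["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} not in expression table")
    total = sub["median_tpm"].sum()
    if total <= 0:
        raise DegenerateInputError(f"gene {gene!r} has zero total expression")
    out = sub.set_index("tissue")["median_tpm"] / total
    out.name = "specificity"
    return out


def epi_evidence(
    lead_snp: str,
    annotation: pd.DataFrame,
    cellline_to_tissue: pd.DataFrame,
    proxies: Sequence[str] = (),
    panel: Optional[ReferencePanel] = None,
    proxy_r2: float = 0.8,
) -> dict[str, str]:
    """Strongest mark per tissue at the lead SNP or any qualifying proxy.

    Proxies count when their r² to the lead (from ``panel``) is at least
    ``proxy_r2``; marks in cell lines not mapped to a tissue are ignored.
    Evidence levels: both > promoter > enhancer > none.
    """
    tissue_of = dict(zip(cellline_to_tissue["cell_line"], cellline_to_tissue["tissue"]))
    snps = {lead_snp}
    for p in proxies:
        if panel is None or (
            lead_snp in panel and p in panel and ld_r2(panel, lead_snp, p) >= proxy_r2
        ):
            snps.add(p)
    marks_per_tissue: dict[str, set] = {}
    hits = annotation[annotation["snp_id"].isin(snps)]
    for r in hits.itertuples():
        tissue = tissue_of.get(r.cell_line)
        if tissue is None:
            continue
        marks_per_tissue.setdefault(tissue, set()).add(r.mark)
    out = {}
    for tissue, marks in marks_per_tissue.items():
        if {"promoter", "enhancer"} <= marks:
            out[tissue] = "both"
        elif "promoter" in marks:
            out[tissue] = "promoter"
        elif "enhancer" in marks:
            out[tissue] = "enhancer"
    return out


def tissue_of_action(
    spec: pd.Series,
    evidence: Mapping[str, str],
    gene: str = "",
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
) -> list[TissueScore]:
    """Ranked tissue scores: score = specificity x weight(evidence).

    Sorted descending by score with ties by specificity then tissue name;
    log10 of a zero score is reported as missing.
    """
    rows = []
    for tissue, s in spec.items():
        ev = evidence.get(tissue, "none")
        score = float(s) * float(weights[ev])
        rows.append((tissue, float(s), ev, score))
    rows.sort(key=lambda r: (-r[3], -r[1], r[0]))
    return [
        TissueScore(
            gene=gene,
            tissue=t,
            specificity=s,
            epi_evidence=ev,
            score=sc,
            log10_score=float(np.log10(sc)) if sc > 0 else None,
            rank=i + 1,
        )
        for i, (t, s, ev, sc) in enumerate(rows)
    ]


def score_gene(
    tpm_table: pd.DataFrame,
    annotation: pd.DataFrame,
    cellline_to_tissue: pd.DataFrame,
    gene: str,
    lead_snp: str,
    proxies: Sequence[str] = (),
    panel: Optional[ReferencePanel] = None,
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Convenience wrapper: specificity + evidence + ranking for one gene."""
    spec = specificity(tpm_table, gene)
    ev = epi_evidence(lead_snp, annotation, cellline_to_tissue, proxies, panel)
    scores = tissue_of_action(spec, ev, gene=gene, weights=weights)
    return pd.DataFrame([s.__dict__ for s in scores])
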