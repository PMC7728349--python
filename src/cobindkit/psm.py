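"""Target-decoy q-values, protein aggregation and interactor filtering.

Scored peptide-to-spectrum matches (PSMs) are handled as a pandas
DataFrame with one row per PSM and the columns

    spectrum_id, peptide, accession, score, delta_cn, is_decoy,
    sample, replicate

(see :data:`PSM_COLUMNS`). ``score`` is the search-engine score (higher
is better), ``is_decoy`` flags matches against the reversed/shuffled
database, ``sample`` is the experimental condition label (e.g.
``benzonase`` / ``untreated`` / ``IgG``) and ``replicate`` the injection
index within that condition.

The false-discovery rate at a score threshold *s* is estimated by the
concatenated target-decoy ratio

    FDR(s) = #{decoys with score >= s} / max(1, #{targets with score >= s})

and each PSM's q-value is the minimum FDR over all thresholds at or
below its score (so q is monotone: a higher score never has a higher
q-value). Protein-level evidence is aggregated as per-injection distinct
peptide and PSM counts, averaged across replicate injections, with the
protein q-value taken as the best (minimum) supporting-PSM q-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PSM_COLUMNS",
    "FilterConfig",
    "compute_psm_qvalues",
    "classify_confidence",
    "apply_delta_cn_filter",
    "aggregate_proteins",
    "filter_interactors",
]

PSM_COLUMNS = (
    "spectrum_id",
    "peptide",
    "accession",
    "score",
    "delta_cn",
    "is_decoy",
    "sample",
    "replicate",
)


@dataclass
class FilterConfig:
    """Thresholds of the PSM validation and interactor filtering stage.

    Defaults follow the conventional strict/relaxed target-decoy setup:
    a maximum Delta Cn of 0.05 for the PSM pre-filter, a strict FDR of
    0.01 defining high-confidence identifications and a relaxed FDR of
    0.05 defining medium confidence.
    """

    max_delta_cn: float = 0.05
    strict_fdr: float = 0.01
    relaxed_fdr: float = 0.05
    contaminants: frozenset = field(default_factory=frozenset)
    control_samples: frozenset = field(default_factory=lambda: frozenset({"IgG"}))

    def __post_init__(self) -> None:
        if not (0.0 < self.strict_fdr < self.relaxed_fdr < 1.0):
            raise ValueError(
                "require 0 < strict_fdr < relaxed_fdr < 1, got "
                f"{self.strict_fdr} / {self.relaxed_fdr}"
            )
        self.contaminants = frozenset(self.contaminants)
        self.control_samples = frozenset(self.control_samples)


def apply_delta_cn_filter(psms: pd.DataFrame, max_delta_cn: float = 0.05) -> pd.DataFrame:
    """Drop PSMs whose delta Cn to the top-ranked candidate exceeds the cap.

    A delta Cn of 0 marks the best candidate for a spectrum; larger
    values mark lower-ranked candidates that scored nearly as well.
    """
    keep = psms["delta_cn"].to_numpy(dtype=float) <= max_delta_cn
    dropped = int((~keep).sum())
    if dropped:
        logger.info("delta Cn filter removed %d of %d PSMs", dropped, len(psms))
    return psms.loc[keep].reset_index(drop=True)


def compute_psm_qvalues(psms: pd.DataFrame) -> pd.DataFrame:
    """Assign target-decoy q-values; returns a copy with a ``q_value`` column.

    Decoy rows receive q-values too (diagnostics only) but downstream
    stages use targets exclusively. With no decoys present the null
    cannot be estimated and all q-values are 0 (a warning is logged).
    """
    out = psms.copy()
    scores = out["score"].to_numpy(dtype=float)
    is_decoy = out["is_decoy"].to_numpy(dtype=bool)
    t_scores = np.sort(scores[~is_decoy])
    d_scores = np.sort(scores[is_decoy])

    if d_scores.size == 0:
        logger.warning("no decoy PSMs present; all q-values set to 0")
        out["q_value"] = 0.0
        return out

    # FDR at every candidate threshold (the distinct target scores,
    # ascending), then the q-value is the running minimum from the
    # lowest threshold up: q(s) = min_{s' <= s} FDR(s').
    thresholds = np.unique(t_scores)
    n_t_ge = t_scores.size - np.searchsorted(t_scores, thresholds, side="left")
    n_d_ge = d_scores.size - np.searchsorted(d_scores, thresholds, side="left")
    fdr = n_d_ge / np.maximum(1, n_t_ge)
    q_at_threshold = np.minimum(np.minimum.accumulate(fdr), 1.0)

    # map every PSM (targets and decoys) to the largest threshold <= score
    idx = np.searchsorted(thresholds, scores, side="right") - 1
    q = np.where(idx >= 0, q_at_threshold[np.clip(idx, 0, None)], 1.0)
    out["q_value"] = q
    return out


def classify_confidence(q: float, cfg: FilterConfig | None = None) -> str:
    """Map a q-value to the ``high`` / ``medium`` / ``rejected`` classes.

    ``high`` below the strict FDR (default 0.01), ``medium`` in
    [strict, relaxed) (default [0.01, 0.05)), ``rejected`` otherwise.
    """
    cfg = cfg or FilterConfig()
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q-value outside [0, 1]: {q}")
    if q < cfg.strict_fdr:
        return "high"
    if q < cfg.relaxed_fdr:
        return "medium"
    return "rejected"


def aggregate_proteins(
    psms: pd.DataFrame, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """Aggregate target PSMs to protein-level evidence per condition.

    For each (accession, sample) pair, distinct-peptide and PSM counts
    are taken per replicate injection and then averaged arithmetically
    across injections. Returns one row per accession with columns

        accession, protein_q, confidence, single_peptide_flag,
        mean_peptides_<sample>, mean_psms_<sample>  (one pair per sample)

    The protein q-value is the minimum q-value among supporting PSMs
    (best-evidence rule); shared peptides contribute to every accession
    they match. Proteins require >= 1 surviving target PSM.
    """
    cfg = cfg or FilterConfig()
    if "q_value" not in psms.columns:
        raise ValueError("run compute_psm_qvalues before aggregate_proteins")
    targets = psms.loc[~psms["is_decoy"].astype(bool)].copy()
    if targets.empty:
        return pd.DataFrame(
            columns=["accession", "protein_q", "confidence", "single_peptide_flag"]
        )

    samples = sorted(targets["sample"].unique())

    per_inj = (
        targets.groupby(["accession", "sample", "replicate"])
        .agg(n_peptides=("peptide", "nunique"), n_psms=("peptide", "size"))
        .reset_index()
    )
    mean_per_sample = (
        per_inj.groupby(["accession", "sample"])[["n_peptides", "n_psms"]]
        .mean()
        .unstack("sample")
    )

    rows: List[dict] = []
    prot_q = targets.groupby("accession")["q_value"].min()
    n_distinct = targets.groupby("accession")["peptide"].nunique()
    for acc in prot_q.index:
        row = {
            "accession": acc,
            "protein_q": float(prot_q[acc]),
            "confidence": classify_confidence(float(prot_q[acc]), cfg),
            "single_peptide_flag": bool(n_distinct[acc] == 1),
        }
        for sample in samples:
            pep = mean_per_sample.loc[acc, ("n_peptides", sample)] if acc in mean_per_sample.index else np.nan
            psm = mean_per_sample.loc[acc, ("n_psms", sample)] if acc in mean_per_sample.index else np.nan
            row[f"mean_peptides_{sample}"] = float(pep) if pd.notna(pep) else 0.0
            row[f"mean_psms_{sample}"] = float(psm) if pd.notna(psm) else 0.0
        rows.append(row)
    result = pd.DataFrame(rows).sort_values("accession").reset_index(drop=True)
    logger.info("aggregated %d PSMs into %d proteins", len(targets), len(result))
    return result


def filter_interactors(
    ip: pd.DataFrame,
    control: pd.DataFrame | None = None,
    cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Retain high-confidence IP proteins absent from controls and contaminants.

    ``ip`` and ``control`` are aggregated protein tables (from
    :func:`aggregate_proteins`). A protein with any evidence in the
    control IP (e.g. the IgG pulldown) is excluded, as is any accession
    on the contaminant list. Idempotent; the output is a subset of ``ip``.
    """
    cfg = cfg or FilterConfig()
    if ip.empty:
        return ip.copy()
    control_accessions = (
        set(control["accession"]) if control is not None and not control.empty else set()
    )
    keep = (
        (ip["confidence"] == "high")
        & ~ip["accession"].isin(control_accessions)
        & ~ip["accession"].isin(cfg.contaminants)
    )
    removed = int((~keep).sum())
    if removed:
        logger.info("interactor filter removed %d of %d proteins", removed, len(ip))
    return ip.loc[keep].reset_index(drop=True)
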