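"""Covariate censoring, taxonomic aggregation and response construction.

The immunoassay censoring rule follows the Luminex convention: a concentration
strictly below the cytokine's lower limit of quantification (LLOQ) is recorded
as 0 pg/ml. The regression response pools all but the ``top_k`` most abundant
genera into a single residual category, so counts are partitioned — per-sample
totals are conserved exactly through every step here.
"""

from __future__ import annotations

import logging

import numpy as np

from .tables import (
    RANKS,
    UNCLASSIFIED,
    CompositionResponse,
    CytokinePanel,
    DesignMatrix,
    LoqTable,
    OtuTable,
    TableError,
)

logger = logging.getLogger(__name__)


def apply_loq(
    panel: CytokinePanel, loq: LoqTable, uloq_policy: str = "flag"
) -> CytokinePanel:
    """Censor a cytokine panel at its quantification limits.

    Values strictly below the LLOQ become 0 pg/ml and are marked in
    ``censored_mask``. Values above the ULOQ are clipped to the ULOQ when
    ``uloq_policy="clip"`` or left in place when ``"flag"``; either way they
    are marked in ``uloq_mask``. Idempotent: censored zeros stay zero.
    """
    if uloq_policy not in ("clip", "flag"):
        raise ValueError(f"uloq_policy must be 'clip' or 'flag', got {uloq_policy!r}")
    missing = [c for c in panel.cytokine_names if c not in loq]
    if missing:
        raise TableError(f"no quantification limits for cytokines: {missing}")
    lo = np.array([loq.lloq[c] for c in panel.cytokine_names])
    hi = np.array([loq.uloq[c] for c in panel.cytokine_names])
    values = panel.values.copy()
    below = values < lo[None, :]
    values[below] = 0.0
    above = values > hi[None, :]
    if uloq_policy == "clip":
        values[above] = np.broadcast_to(hi[None, :], values.shape)[above]
    return CytokinePanel(
        values,
        list(panel.sample_ids),
        list(panel.cytokine_names),
        censored_mask=below | panel.censored_mask,
        uloq_mask=above | panel.uloq_mask,
    )


def aggregate_to_rank(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts across taxa sharing a label at the given taxonomic rank.

    Taxa unclassified at that rank are pooled into ``unclassified_<rank>``.
    Per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    labels = []
    for t in table.taxon_ids:
        lineage = table.taxonomy.get(t, (UNCLASSIFIED,) * len(RANKS))
        label = lineage[level] if level < len(lineage) else UNCLASSIFIED
        if label == UNCLASSIFIED or not label:
            label = f"{UNCLASSIFIED}_{rank}"
        labels.append(label)
    uniq = sorted(set(labels))
    col_of = {g: i for i, g in enumerate(uniq)}
    out = np.zeros((table.n_samples, len(uniq)), dtype=np.int64)
    for j, g in enumerate(labels):
        out[:, col_of[g]] += table.counts[:, j]
    taxonomy = {}
    for g in uniq:
        lineage = [UNCLASSIFIED] * len(RANKS)
        lineage[level] = g
        taxonomy[g] = tuple(lineage)
    return OtuTable(out, list(table.sample_ids), uniq, taxonomy)


def build_composition_response(genus_table: OtuTable, top_k: int = 3) -> CompositionResponse:
    """Build the J = top_k + 1 category response: top genera plus residual.

    Ranking is by total count across the table's samples; ties are broken
    lexicographically (and logged). Everything outside the top ``top_k`` is
    summed into the final ``"residual"`` category.
    """
    if top_k < 1:
        raise ValueError("top_k must be positive")
    totals = genus_table.counts.sum(axis=0)
    nonzero = int((totals > 0).sum())
    if nonzero < top_k + 1:
        raise TableError(
            f"need more than top_k={top_k} genera with nonzero totals, have {nonzero}"
        )
    order = sorted(
        range(genus_table.n_taxa),
        key=lambda j: (-totals[j], genus_table.taxon_ids[j]),
    )
    top = order[:top_k]
    if top_k < len(order) and totals[order[top_k - 1]] == totals[order[top_k]]:
        logger.info(
            "tie at the top-%d boundary broken lexicographically (%s kept)",
            top_k, genus_table.taxon_ids[order[top_k - 1]],
        )
    rest = order[top_k:]
    counts = np.column_stack(
        [genus_table.counts[:, j] for j in top]
        + [genus_table.counts[:, rest].sum(axis=1)]
    )
    names = [genus_table.taxon_ids[j] for j in top] + ["residual"]
    return CompositionResponse(counts, list(genus_table.sample_ids), names)


def standardize_covariates(
    panel: CytokinePanel, transform: str = "log1p_zscore"
) -> DesignMatrix:
    """Build a regression design matrix from a cytokine panel.

    ``log1p_zscore`` (default) applies log(1 + x) then per-column z-scoring —
    pg/ml scales are right-skewed and would otherwise dominate the log link.
    ``zscore`` standardizes the raw values; ``none`` leaves them untouched.
    An intercept column of ones is always prepended.
    """
    if transform not in ("log1p_zscore", "zscore", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    V = panel.values.astype(float)
    if transform == "log1p_zscore":
        V = np.log1p(V)
    if transform in ("log1p_zscore", "zscore"):
        sd = V.std(axis=0, ddof=0)
        dead = np.where(sd == 0)[0]
        if dead.size:
            names = [panel.cytokine_names[j] for j in dead]
            raise ValueError(f"zero-variance cytokine(s) under {transform!r}: {names}")
        V = (V - V.mean(axis=0)) / sd
    X = np.column_stack([np.ones(V.shape[0]), V])
    return DesignMatrix(X, list(panel.sample_ids), list(panel.cytokine_names), transform)
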