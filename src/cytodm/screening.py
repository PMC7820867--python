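"""Sure-independence screening of cytokines by marginal Dirichlet regression.

Each cytokine is scored on its own: a Dirichlet regression with that cytokine
as the only predictor is tested against the intercept-only model by a
likelihood-ratio test on J degrees of freedom (one coefficient per response
category). Cytokines are ranked by ascending p-value — ties broken by
descending statistic, then name — and the top m advance to the joint
Bayesian variable-selection step. The p-values are used for ranking only; no
multiple-testing correction is applied and none is implied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dirichlet import (
    counts_to_proportions,
    fit_dirichlet_regression,
    fit_dm_regression,
    lrt_pvalue,
)
from .preprocess import standardize_covariates
from .tables import CompositionResponse, CytokinePanel

logger = logging.getLogger(__name__)

__all__ = ["ScreeningResult", "screen_cytokines", "select_top"]


@dataclass
class ScreeningResult:
    """Per-cytokine marginal evidence and the resulting ranking."""

    table: pd.DataFrame  # columns: statistic, p_value, rank, converged
    m: int
    selection: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["selected"] = out.index.isin(self.selection)
        return out


def screen_cytokines(
    panel: CytokinePanel,
    response: CompositionResponse,
    transform: str = "log1p_zscore",
    pseudocount: float = 0.5,
    m: int = 3,
    likelihood: str = "dirichlet",
) -> ScreeningResult:
    """Rank cytokines by single-predictor Dirichlet-regression LRT p-values.

    ``panel`` and ``response`` must cover the same samples (any order; the
    panel's order wins). Non-convergent fits get p = 1 and a warning rather
    than aborting the screen. ``m`` sets how many top cytokines are selected.
    ``likelihood="dm"`` screens on the Dirichlet-multinomial likelihood of
    the raw counts instead of the pseudocount-proportions Dirichlet density
    — the sensitivity path for zero-heavy or shallow tables.
    """
    if len(panel.cytokine_names) < 2:
        raise ValueError("need at least 2 cytokines to screen")
    if set(panel.sample_ids) != set(response.sample_ids):
        raise ValueError("panel and response sample ids do not align")
    if likelihood not in ("dirichlet", "dm"):
        raise ValueError(f"unknown likelihood {likelihood!r}")
    response = response.select_samples(list(panel.sample_ids))
    J = response.n_categories
    n = len(panel.sample_ids)
    if likelihood == "dirichlet":
        P = counts_to_proportions(response.counts, pseudocount)
        fit_fn = lambda X: fit_dirichlet_regression(X, P)  # noqa: E731
    else:
        fit_fn = lambda X: fit_dm_regression(X, response.counts)  # noqa: E731
    null_fit = fit_fn(np.ones((n, 1)))
    rows = []
    any_converged = False
    for k, name in enumerate(panel.cytokine_names):
        x = panel.values[:, k].astype(float)
        if transform == "log1p_zscore":
            x = np.log1p(x)
        if transform in ("log1p_zscore", "zscore"):
            sd = x.std()
            if sd == 0:
                logger.warning("cytokine %s is constant; assigned p = 1", name)
                rows.append((name, 0.0, 1.0, False))
                continue
            x = (x - x.mean()) / sd
        X = np.column_stack([np.ones(n), x])
        fit = fit_fn(X)
        if not fit.converged:
            logger.warning("single-cytokine fit for %s did not converge; p = 1", name)
            rows.append((name, 0.0, 1.0, False))
            continue
        stat, p = lrt_pvalue(fit, null_fit, df=J)
        any_converged = True
        rows.append((name, stat, p, True))
    if not any_converged:
        raise RuntimeError("no single-cytokine fit converged; screening impossible")
    df = pd.DataFrame(rows, columns=["cytokine", "statistic", "p_value", "converged"])
    df = df.set_index("cytokine")
    order = df.sort_values(
        by=["p_value", "statistic", "cytokine"],
        ascending=[True, False, True],
        kind="mergesort",
    ).index
    df["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order, dtype=int
    )
    df = df.loc[list(panel.cytokine_names)]
    result = ScreeningResult(table=df, m=m)
    result.selection = select_top(result, m)
    return result


def select_top(result: ScreeningResult, m: int) -> list[str]:
    """Names of the m best-ranked cytokines, in rank order."""
    K = len(result.table)
    if not (1 <= m <= K):
        raise ValueError(f"m must be in [1, {K}], got {m}")
    ranked = result.table.sort_values("rank").index
    return list(ranked[:m])
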