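"""Balanced repeated replication (BRR) variance for complex-survey statistics.

Public-use survey files mask the design down to a stratum id and two
primary sampling units (PSUs) per stratum.  BRR forms half-samples by
picking one PSU per stratum; with Fay's adjustment the selected PSU's
respondents have their weights multiplied by (2 - k) and the others by k
(here k = 0.3 by default), which keeps every respondent in every replicate
and stabilizes ratio statistics.  Half-sample selection follows the rows of
a Hadamard matrix so that replicates are balanced: each stratum's signs sum
to zero across replicates, and the variance of any statistic theta is

    var(theta) = 1 / (R * (1 - k)^2) * sum_r (theta_r - theta_hat)^2

with theta_hat computed under the base weights.

Strata with more than two PSUs are collapsed into pseudo-pairs by PSU
order (logged); strata with a single PSU are an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import hadamard

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateWeightSet",
    "ContrastResult",
    "TrendResult",
    "DesignError",
    "build_replicates",
    "brr_se",
    "pairwise_contrast",
    "trend_test",
    "results_to_frame",
]


class DesignError(ValueError):
    """Raised for designs BRR cannot handle (e.g. singleton-PSU strata)."""


@dataclass(frozen=True)
class ReplicateWeightSet:
    """Base weights plus R Fay-adjusted replicate weight vectors.

    ``replicates`` has one row per respondent (indexed by respondent id)
    and one column per replicate; ``assignment`` records the +/-1 Hadamard
    sign of each pseudo-stratum in each replicate; ``design_df`` is the
    complex-survey degrees of freedom (#PSUs - #strata).
    """

    base: pd.Series
    replicates: pd.DataFrame
    fay_k: float
    assignment: pd.DataFrame
    design_df: int

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]


@dataclass(frozen=True)
class ContrastResult:
    """A BRR-tested difference between two group statistics."""

    pair: tuple[str, str]
    estimate: float
    se: float
    statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class TrendResult:
    """BRR-weighted linear trend of a cycle-level statistic over time."""

    slope: float
    se: float
    statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _pseudo_pairs(respondents: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Assign each respondent a pseudo-stratum index and half (0/1).

    Strata must have >= 2 PSUs; pairs are formed in PSU sort order, and an
    odd trailing PSU joins the final pair (logged).  Returns the assignment
    frame plus (#distinct PSUs, #pseudo-strata).
    """
    out = respondents.loc[:, ["respondent_id", "stratum", "psu"]].copy()
    out["pseudo_stratum"] = -1
    out["half"] = -1
    n_pseudo = 0
    n_psus = 0
    for stratum, sub in out.groupby("stratum", sort=True):
        psus = sorted(sub["psu"].unique())
        n_psus += len(psus)
        if len(psus) < 2:
            raise DesignError(
                f"stratum {stratum!r} has a single PSU; BRR needs two per stratum"
            )
        if len(psus) > 2:
            logger.warning(
                "stratum %r has %d PSUs; collapsing into pseudo-pairs by PSU order",
                stratum, len(psus),
            )
        half_of: dict[object, tuple[int, int]] = {}
        n_even = len(psus) - (len(psus) % 2)
        for i, psu in enumerate(psus):
            # an odd trailing PSU joins the final pair
            pair_idx = i // 2 if i < n_even else (len(psus) // 2) - 1
            half_of[psu] = (n_pseudo + pair_idx, i % 2)
        mask = out["stratum"] == stratum
        out.loc[mask, "pseudo_stratum"] = out.loc[mask, "psu"].map(lambda p: half_of[p][0])
        out.loc[mask, "half"] = out.loc[mask, "psu"].map(lambda p: half_of[p][1])
        n_pseudo += len(psus) // 2
    return out, n_psus, n_pseudo


def _hadamard_order(n_strata: int) -> int:
    # smallest Sylvester order with n_strata usable (zero-sum) columns:
    # the all-ones column cannot serve a stratum, so order > n_strata
    order = 1
    while order <= n_strata:
        order *= 2
    return max(order, 2)


def build_replicates(
    respondents: pd.DataFrame,
    fay_k: float = 0.3,
    hadamard_order: int | None = None,
) -> ReplicateWeightSet:
    """Construct Fay-adjusted BRR replicate weights from masked design ids.

    Each pseudo-stratum is assigned a distinct zero-sum column of a
    Hadamard matrix of the requested order (default: the smallest
    power-of-two order exceeding the number of pseudo-strata); the matrix
    rows define the replicates.  Within a replicate, respondents in the
    selected half get weight ``base * (2 - fay_k)`` and the others
    ``base * fay_k``; ``fay_k=0`` reduces to classic BRR factors {2, 0}.
    """
    if not 0 <= fay_k < 1:
        raise DesignError(f"fay_k must be in [0, 1), got {fay_k}")
    assign, n_psus, n_pseudo = _pseudo_pairs(respondents)
    order = hadamard_order if hadamard_order is not None else _hadamard_order(n_pseudo)
    if order <= n_pseudo:
        raise DesignError(
            f"Hadamard order {order} cannot seat {n_pseudo} strata on zero-sum columns"
        )
    H = hadamard(order)
    # column c+1 serves pseudo-stratum c; rows are replicates
    signs = H[:, 1 : n_pseudo + 1]  # (R, n_pseudo)

    ids = respondents["respondent_id"].astype(str).to_numpy()
    base = pd.Series(respondents["day1_weight"].to_numpy(float), index=ids, name="base")
    ps = assign["pseudo_stratum"].to_numpy(int)
    half = assign["half"].to_numpy(int)
    # respondent is "selected" in replicate r when sign matches its half
    sel = signs[:, ps].T == np.where(half == 0, 1, -1)[:, None]  # (n, R)
    factors = np.where(sel, 2.0 - fay_k, fay_k)
    replicates = pd.DataFrame(
        base.to_numpy()[:, None] * factors,
        index=ids,
        columns=[f"rep{r}" for r in range(order)],
    )
    assignment = pd.DataFrame(
        signs.T, index=[f"pseudo{c}" for c in range(n_pseudo)],
        columns=replicates.columns,
    )
    return ReplicateWeightSet(
        base=base,
        replicates=replicates,
        fay_k=fay_k,
        assignment=assignment,
        design_df=n_psus - n_pseudo,
    )


def brr_se(
    statistic_fn: Callable[[object, pd.Series], float],
    data: object,
    replicates: ReplicateWeightSet,
) -> float:
    """BRR standard error of ``statistic_fn(data, weights)``.

    ``SE^2 = (1 / (R (1-k)^2)) * sum_r (theta_r - theta_hat)^2`` with
    theta_hat evaluated under the base weights.
    """
    theta_hat = statistic_fn(data, replicates.base)
    deviations = np.empty(replicates.n_replicates)
    for r, col in enumerate(replicates.replicates.columns):
        try:
            theta_r = statistic_fn(data, replicates.replicates[col])
        except Exception as exc:
            raise RuntimeError(f"statistic failed on replicate {r}") from exc
        deviations[r] = theta_r - theta_hat
    R = replicates.n_replicates
    return float(
        np.sqrt(np.sum(deviations**2) / (R * (1.0 - replicates.fay_k) ** 2))
    )


def _t_pvalue(estimate: float, se: float, df: int) -> tuple[float, float]:
    if se == 0:
        return (0.0, 1.0) if estimate == 0 else (np.inf, 0.0)
    stat = estimate / se
    return stat, float(2 * sps.t.sf(abs(stat), df))


def pairwise_contrast(
    scores_by_outlet_fn: Callable[[object, pd.Series], Mapping[str, float]],
    data: object,
    replicates: ReplicateWeightSet,
    pair: tuple[str, str],
) -> ContrastResult:
    """Two-sided BRR t-test of the difference between two outlet scores.

    The difference is treated as a single statistic per replicate; degrees
    of freedom follow the complex-survey rule #PSUs - #strata.
    """
    a, b = pair
    base_scores = scores_by_outlet_fn(data, replicates.base)
    for name in pair:
        if name not in base_scores:
            raise DesignError(f"outlet {name!r} missing from scores")
    estimate = base_scores[a] - base_scores[b]

    def diff_fn(d: object, w: pd.Series) -> float:
        s = scores_by_outlet_fn(d, w)
        return s[a] - s[b]

    se = brr_se(diff_fn, data, replicates)
    stat, p = _t_pvalue(estimate, se, replicates.design_df)
    return ContrastResult(
        pair=pair, estimate=estimate, se=se, statistic=stat,
        df=replicates.design_df, p_value=p,
    )


def trend_test(
    score_fn: Callable[[object, pd.Series], float],
    data_by_cycle: Sequence[object],
    replicates_by_cycle: Sequence[ReplicateWeightSet],
) -> TrendResult:
    """BRR-weighted linear trend of a cycle-level statistic over time.

    The statistic is computed per cycle under base weights and regressed on
    the cycle index 0..C-1 (OLS slope); replicate r recomputes the slope
    with replicate-r weights in every cycle, and the BRR formula gives the
    slope's standard error.  Requires >= 3 cycles and a common replicate
    count R across cycles (each cycle keeps its own replicate set).
    """
    C = len(data_by_cycle)
    if C < 3:
        raise DesignError(f"trend test needs >= 3 cycles, got {C}")
    if len(replicates_by_cycle) != C:
        raise DesignError("one replicate set per cycle is required")
    Rs = {rep.n_replicates for rep in replicates_by_cycle}
    if len(Rs) > 1:
        raise DesignError(f"cycles have differing replicate counts: {sorted(Rs)}")
    ks = {rep.fay_k for rep in replicates_by_cycle}
    if len(ks) > 1:
        raise DesignError("cycles have differing Fay coefficients")
    (R,), (k,) = Rs, ks

    x = np.arange(C, dtype=float)
    xc = x - x.mean()

    def slope_of(scores: np.ndarray) -> float:
        # centered OLS slope; exact zero for constant scores
        return float(np.dot(xc, scores - scores.mean()) / np.dot(xc, xc))

    base_scores = np.array(
        [score_fn(d, rep.base) for d, rep in zip(data_by_cycle, replicates_by_cycle)]
    )
    slope_hat = slope_of(base_scores)
    dev = np.empty(R)
    for r in range(R):
        scores_r = np.array(
            [
                score_fn(d, rep.replicates.iloc[:, r])
                for d, rep in zip(data_by_cycle, replicates_by_cycle)
            ]
        )
        dev[r] = slope_of(scores_r) - slope_hat
    se = float(np.sqrt(np.sum(dev**2) / (R * (1.0 - k) ** 2)))
    df = int(sum(rep.design_df for rep in replicates_by_cycle))
    stat, p = _t_pvalue(slope_hat, se, df)
    return TrendResult(slope=slope_hat, se=se, statistic=stat, df=df, p_value=p)


def results_to_frame(results: Sequence[ContrastResult | TrendResult]) -> pd.DataFrame:
    """Tabulate contrast/trend results for CSV export."""
    rows = []
    for res in results:
        label = "/".join(res.pair) if isinstance(res, ContrastResult) else "trend"
        est = res.estimate if isinstance(res, ContrastResult) else res.slope
        rows.append(
            {
                "comparison": label,
                "estimate": est,
                "se": res.se,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
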