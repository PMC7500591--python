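"""Treatment-effect estimation for plant traits.

Ordinary least squares with water treatment as a nominal factor and
optional plot-ID fixed-effect blocks, the standard analysis for
drought-trial growth measurements (height in meters, seed weight in
grams, cob diameter in millimeters).  Effects are reported as the
reduction under drought (watered minus drought; positive = smaller under
drought).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger("phyllodiff")

TRAIT_COLUMNS = ("site", "plot_id", "treatment", "trait_name", "value", "units")


@dataclass(frozen=True)
class TraitFit:
    """Treatment effect for one trait: estimate, inference and group summaries."""

    effect: float            # watered - drought, trait units
    se: float
    p: float
    group_means: dict
    group_ns: dict
    percent_reduction: float  # effect / watered mean * 100
    significant: bool
    include_blocks: bool
    trait_name: str = ""
    units: str = ""

    def ci95(self) -> tuple[float, float]:
        return (self.effect - 1.96 * self.se, self.effect + 1.96 * self.se)


def read_trait_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(TRAIT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trait table lacks columns {sorted(missing)}")
    return frame


def exclude_rows(
    table: pd.DataFrame,
    zero_values: bool = False,
    plot_ids=(),
    predicate=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply declarative exclusion rules, returning (kept, removed).

    Rules: drop rows with a zero trait value (e.g. cobs that set no
    seed), drop whole plots by ID (e.g. a plot invalidated by unmanaged
    rain), or an arbitrary boolean predicate on rows (True = remove).
    Removing every row of a treatment level is an error; the removed rows
    are returned for the audit trail.
    """
    mask = pd.Series(False, index=table.index)
    if zero_values:
        mask |= table["value"] == 0
    if len(list(plot_ids)):
        mask |= table["plot_id"].isin(list(plot_ids))
    if predicate is not None:
        mask |= table.apply(predicate, axis=1).astype(bool)
    kept, removed = table[~mask], table[mask]
    if len(removed):
        logger.info("excluded %d trait rows", len(removed))
    before = set(table["treatment"])
    after = set(kept["treatment"])
    lost = before - after
    if lost:
        raise ValueError(f"exclusion removed every row of treatment level(s) {sorted(lost)}")
    return kept, removed


def fit_trait(table: pd.DataFrame, include_blocks: bool = False, alpha: float = 0.05) -> TraitFit:
    """OLS treatment effect for one trait table.

    The model is ``value ~ treatment`` with optional ``C(plot_id)``
    fixed-effect blocks (no treatment x plot interaction).  With balanced
    groups and no blocks the estimate equals the difference of group
    means exactly.  The effect sign is watered minus drought.
    """
    levels = sorted(table["treatment"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two treatment levels, got {levels}")
    counts = table["treatment"].value_counts()
    if (counts < 2).any():
        raise ValueError("need >= 2 observations per treatment level")
    if not np.isfinite(table["value"]).all():
        raise ValueError("trait values must be finite")

    data = table.copy()
    # make 'watered' the reference level so the coefficient is drought - watered
    ref = "watered" if "watered" in levels else levels[0]
    other = [l for l in levels if l != ref][0]
    data["treatment"] = pd.Categorical(data["treatment"], categories=[ref, other])

    formula = "value ~ treatment"
    if include_blocks:
        formula += " + C(plot_id)"
    fit = smf.ols(formula, data=data).fit()
    term = f"treatment[T.{other}]"
    if term not in fit.params.index or not np.isfinite(fit.bse[term]):
        raise ValueError("block structure is collinear with treatment; cannot estimate the effect")
    coef = float(fit.params[term])       # other - ref, i.e. drought - watered
    se = float(fit.bse[term])
    p = float(fit.pvalues[term])

    group_means = data.groupby("treatment", observed=True)["value"].mean().to_dict()
    group_ns = data.groupby("treatment", observed=True)["value"].size().to_dict()
    effect = -coef  # reported as reduction under drought (watered - drought)
    watered_mean = group_means.get("watered", group_means[ref])
    pct = effect / watered_mean * 100.0 if watered_mean else float("nan")

    name = table["trait_name"].iloc[0] if "trait_name" in table else ""
    units = table["units"].iloc[0] if "units" in table else ""
    return TraitFit(
        effect=effect, se=se, p=p,
        group_means={str(k): float(v) for k, v in group_means.items()},
        group_ns={str(k): int(v) for k, v in group_ns.items()},
        percent_reduction=float(pct), significant=bool(p < alpha),
        include_blocks=include_blocks, trait_name=str(name), units=str(units))
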