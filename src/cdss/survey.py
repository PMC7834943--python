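"""Usability-instrument statistics: Likert summaries and Cronbach alpha.

The evaluation instrument has 24 Likert items (1 = strongly disagree … 5
= strongly agree) grouped into four dimensions — feasibility, usability,
utility, satisfaction — answered by three professional groups.  This
module computes per-item medians with interquartile ranges by group and
the internal-consistency coefficient

    alpha = k/(k-1) * (1 - sum_i var_i / var_total)

globally and per dimension.  Conventions, fixed and documented because
the printed tables cannot disambiguate them: sample (n-1) variances,
listwise deletion of incomplete respondents, quartiles by linear
interpolation.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

DIMENSIONS = ("feasibility", "usability", "utility", "satisfaction")
GROUPS = ("physician", "nurse", "nasf")

#: Default item -> dimension map for the 24-item instrument (six items per
#: dimension, in questionnaire order).
DEFAULT_DIMENSION_MAP: dict[str, str] = {
    f"item_{i:02d}": DIMENSIONS[(i - 1) // 6] for i in range(1, 25)
}


class SurveyError(ValueError):
    pass


class LikertResponseSet:
    """Respondents × items matrix with group and dimension labels."""

    def __init__(
        self,
        responses: pd.DataFrame,
        groups: Sequence[str],
        dimension_map: Optional[Mapping[str, str]] = None,
    ) -> None:
        values = responses.to_numpy(dtype=float)
        valid = np.isnan(values) | ((values >= 1) & (values <= 5)
                                    & (values == np.round(values)))
        if not valid.all():
            raise SurveyError("responses must be integers 1..5 or missing")
        if dimension_map is None:
            if set(responses.columns) == set(DEFAULT_DIMENSION_MAP):
                dimension_map = dict(DEFAULT_DIMENSION_MAP)
            else:
                raise SurveyError("dimension_map required for non-default items")
        missing = set(responses.columns) - set(dimension_map)
        if missing:
            raise SurveyError(f"items without a dimension: {sorted(missing)}")
        if len(groups) != len(responses):
            raise SurveyError("one group label per respondent required")
        self.responses = responses.reset_index(drop=True)
        self.groups = pd.Series(list(groups), name="group")
        self.dimension_map = dict(dimension_map)

    @classmethod
    def from_csv(cls, path, dimension_map: Optional[Mapping[str, str]] = None
                 ) -> "LikertResponseSet":
        """Read ``respondent_id,group,item_...`` CSV."""
        df = pd.read_csv(path)
        item_cols = [c for c in df.columns
                     if c not in ("respondent_id", "group")]
        return cls(df[item_cols], df["group"].tolist(), dimension_map)

    def items(self, dimension: Optional[str] = None) -> list[str]:
        if dimension is None:
            return list(self.responses.columns)
        return [c for c in self.responses.columns
                if self.dimension_map[c] == dimension]

    def group_proportions(self) -> pd.DataFrame:
        """Respondent counts and percentages per professional group.

        Percentages use half-up rounding to whole percent alongside the
        exact two-decimal value.
        """
        counts = self.groups.value_counts()
        n = int(counts.sum())
        rows = []
        for group, count in counts.items():
            exact = 100.0 * count / n
            rows.append({"group": group, "n": int(count),
                         "pct": round(exact, 2),
                         "pct_printed": int(np.floor(exact + 0.5))})
        return pd.DataFrame(rows).set_index("group")


def cronbach_alpha(
    response_set: Union[LikertResponseSet, pd.DataFrame, np.ndarray],
    items: Optional[Sequence[str]] = None,
    dimension: Optional[str] = None,
) -> float:
    """Cronbach alpha for an item subset (default: all items).

    Incomplete respondents are dropped listwise; variances use the sample
    (n-1) denominator throughout so the item and total variances share a
    convention.  Raises on fewer than 2 items, fewer than 2 complete
    respondents, or zero total variance.
    """
    if isinstance(response_set, LikertResponseSet):
        if dimension is not None:
            if items is not None:
                raise SurveyError("pass either items or dimension, not both")
            items = response_set.items(dimension)
        data = response_set.responses[list(items)] if items is not None \
            else response_set.responses
    else:
        data = pd.DataFrame(response_set)
        if items is not None:
            data = data[list(items)]
    matrix = data.dropna(axis=0, how="any").to_numpy(dtype=float)
    n, k = matrix.shape
    if k < 2:
        raise SurveyError("alpha needs at least 2 items")
    if n < 2:
        raise SurveyError("alpha needs at least 2 complete respondents")
    item_vars = matrix.var(axis=0, ddof=1)
    total_var = matrix.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise SurveyError("zero total-score variance")
    return (k / (k - 1)) * (1.0 - item_vars.sum() / total_var)


def alpha_by_dimension(response_set: LikertResponseSet) -> dict[str, float]:
    """Alpha for the global scale and each dimension separately."""
    out = {"global": cronbach_alpha(response_set)}
    for dim in DIMENSIONS:
        if response_set.items(dim):
            out[dim] = cronbach_alpha(response_set, dimension=dim)
    return out


def likert_summary(response_set: LikertResponseSet) -> pd.DataFrame:
    """Median and IQR per item, per professional group and overall.

    Quartiles use linear interpolation; the ``display`` column renders
    the printed style ``median (q1-q3)``.
    """
    frames = []
    df = response_set.responses

    def summarize(sub: pd.DataFrame, label: str) -> None:
        for item in df.columns:
            col = sub[item].dropna()
            if col.empty:
                continue
            med = float(np.median(col))
            q1 = float(np.percentile(col, 25))
            q3 = float(np.percentile(col, 75))
            frames.append({
                "item": item,
                "dimension": response_set.dimension_map[item],
                "group": label, "n": int(col.size),
                "median": med, "q1": q1, "q3": q3,
                "display": f"{med:g} ({q1:g}-{q3:g})",
            })

    summarize(df, "all")
    for group in pd.unique(response_set.groups):
        summarize(df[(response_set.groups == group).to_numpy()], group)
    return pd.DataFrame(frames)
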