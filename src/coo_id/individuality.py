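"""Individuality statistics: corrected CV, PIC, and nonparametric screening.

The coefficient of variation carries the small-sample correction
CV = 100·(1 + 1/4n)·SD/x̄ (sample SD, n-1 denominator).  For each acoustic
parameter the potential for individual identity coding is
PIC = CV_b / mean(CV_w): the between-individual CV divided by the unweighted
mean of the per-individual within CVs.  PIC > 1 marks a parameter that varies
more between callers than within a caller, i.e. one that could encode
identity.

Screening mirrors the standard nonparametric route: a Kruskal–Wallis test per
parameter across individuals, and — only when that is significant — all
pairwise Mann–Whitney U tests at a Bonferroni-adjusted level
family_alpha / C(k, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import PARAMETERS

BETWEEN_MODES = ("pooled_calls", "individual_means")


class FeatureTableError(ValueError):
    """Feature table does not satisfy the analysis preconditions."""


def validate_feature_table(table: pd.DataFrame, parameters=PARAMETERS) -> None:
    """Check the calls × parameters matrix: ≥2 individuals, ≥2 calls each, no NaN."""
    if "individual_id" not in table.columns:
        raise FeatureTableError("feature table needs an 'individual_id' column")
    missing = [p for p in parameters if p not in table.columns]
    if missing:
        raise FeatureTableError(f"feature table lacks parameters: {missing}")
    counts = table["individual_id"].value_counts()
    if len(counts) < 2:
        raise FeatureTableError("need at least 2 individuals")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise FeatureTableError(f"every individual needs >= 2 calls; too few for {small}")
    if table[list(parameters)].isna().any().any():
        raise FeatureTableError("feature table contains missing values")


def corrected_cv(values) -> float:
    """Small-sample-corrected coefficient of variation, in percent.

    CV = 100 · (1 + 1/(4n)) · SD/x̄ with the sample (n-1) SD.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"CV needs n >= 2 values, got {v.size}")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(100.0 * (1.0 + 1.0 / (4.0 * v.size)) * np.std(v, ddof=1) / mean)


def pic_table(
    table: pd.DataFrame,
    between_mode: str = "pooled_calls",
    parameters=PARAMETERS,
) -> pd.DataFrame:
    """Per-parameter mean CV_w, CV_b and PIC = CV_b / mean CV_w.

    ``between_mode='pooled_calls'`` computes CV_b over all calls pooled;
    ``'individual_means'`` computes it over the per-individual means.  mean
    CV_w is the unweighted mean of per-individual CVs.  A parameter for which
    some individual has zero within-individual SD gets PIC = NaN (reported,
    not dropped).
    """
    if between_mode not in BETWEEN_MODES:
        raise ValueError(f"between_mode must be one of {BETWEEN_MODES}")
    validate_feature_table(table, parameters)
    groups = table.groupby("individual_id", sort=True)
    rows = []
    for p in parameters:
        cv_w = [corrected_cv(g[p].to_numpy()) for _, g in groups]
        mean_cv_w = float(np.mean(cv_w))
        if between_mode == "pooled_calls":
            cv_b = corrected_cv(table[p].to_numpy())
        else:
            cv_b = corrected_cv(groups[p].mean().to_numpy())
        pic = cv_b / mean_cv_w if mean_cv_w > 0 else np.nan
        rows.append({"parameter": p, "mean_cv_w": mean_cv_w, "cv_b": cv_b, "pic": pic})
    return pd.DataFrame(rows)


def kw_screen(table: pd.DataFrame, parameter: str) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p across individuals."""
    groups = [g[parameter].to_numpy() for _, g in table.groupby("individual_id", sort=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise FeatureTableError("Kruskal-Wallis needs >= 2 groups of >= 2 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise FeatureTableError(f"{parameter}: all values identical, ranks degenerate")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _mwu_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U and p: exact for small tie-free samples,
    normal approximation with tie/continuity correction otherwise."""
    exact = (
        len(a) <= 8 and len(b) <= 8
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PairwiseTestResult:
    """Screening result for one parameter."""

    parameter: str
    h_statistic: float
    p_value: float
    adjusted_alpha: float
    detected_pairs: list[tuple[str, str]] = field(default_factory=list)
    pair_p_values: dict = field(default_factory=dict)

    @property
    def kw_significant(self) -> bool:
        return self.p_value < 0.05


def pairwise_mwu(
    table: pd.DataFrame, parameter: str, family_alpha: float = 0.05
) -> PairwiseTestResult:
    """All C(k,2) pairwise Mann–Whitney U tests at the Bonferroni level.

    A pair is detected iff its two-tailed p is below family_alpha / C(k,2)
    (0.05/21 = 0.002 for seven individuals).  The Kruskal–Wallis result is
    carried along; callers normally gate on it (see :func:`screen_parameters`).
    """
    h, kw_p = kw_screen(table, parameter)
    groups = {gid: g[parameter].to_numpy()
              for gid, g in table.groupby("individual_id", sort=True)}
    ids = sorted(groups)
    n_pairs = len(ids) * (len(ids) - 1) // 2
    adjusted = family_alpha / n_pairs
    detected, pair_ps = [], {}
    for a, b in combinations(ids, 2):
        _, p = _mwu_p(groups[a], groups[b])
        pair_ps[(a, b)] = p
        if p < adjusted:
            detected.append((a, b))
    return PairwiseTestResult(
        parameter=parameter, h_statistic=h, p_value=kw_p,
        adjusted_alpha=adjusted, detected_pairs=detected, pair_p_values=pair_ps,
    )


def screen_parameters(
    table: pd.DataFrame, family_alpha: float = 0.05, parameters=PARAMETERS
) -> pd.DataFrame:
    """KW screen per parameter; pairwise MWU only where KW is significant.

    Returns the screening table: parameter, chi2, p, detected_pairs (pairs
    serialized ``"A-B;C-D"``, empty when the KW gate is not passed).
    """
    validate_feature_table(table, parameters)
    rows = []
    for p in parameters:
        res = pairwise_mwu(table, p, family_alpha)
        pairs = (
            ";".join(f"{a}-{b}" for a, b in res.detected_pairs)
            if res.kw_significant else ""
        )
        rows.append({
            "parameter": p,
            "chi2": res.h_statistic,
            "p": res.p_value,
            "detected_pairs": pairs,
            "adjusted_alpha": res.adjusted_alpha,
        })
    return pd.DataFrame(rows)
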