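"""Nonparametric feature screening: Mann-Whitney U and single-feature AUC.

Each feature is screened independently with the two-sample Mann-Whitney
U test (patients vs. controls) and the probability-definition AUC: the
probability that a randomly selected patient has a higher value of the
feature than a randomly selected control, ties counting half.  The AUC
is exactly U / (n_patients * n_controls).

Features are kept when they clear either of two strict cutoffs
(defaults p <= 1e-5 or orientation-corrected AUC >= 0.9); the two pass
lists are reported separately.  The AUC cutoff is applied to
max(auc, 1 - auc) because clinically informative features deviate in
both directions — e.g. the rate of inversion in pressure is *lower* in
patients, whose smooth tremor oscillation produces one inversion per
half-period while a steady hand's fine fluctuation flips sign almost
every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io_tablet import META_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_P_CUT = 1e-5
DEFAULT_AUC_CUT = 0.9

#: product of group sizes below which the exact U null distribution is used
_EXACT_LIMIT = 400


def _clean_groups(
    patient_values: np.ndarray, control_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(patient_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    pf, cf = p[np.isfinite(p)], c[np.isfinite(c)]
    n_dropped = (p.size - pf.size) + (c.size - cf.size)
    if n_dropped:
        logger.debug("screening: dropped %d NaN values", n_dropped)
    if pf.size == 0 or cf.size == 0:
        raise ValueError("a group is empty after NaN removal")
    return pf, cf


def feature_auc(patient_values: np.ndarray, control_values: np.ndarray) -> float:
    """AUC = P(patient value > control value), ties counting half.

    Computed from midranks so it equals U / (n_p * n_c) exactly; NaNs
    are excluded per group before ranking.
    """
    p, c = _clean_groups(patient_values, control_values)
    ranks = sp_stats.rankdata(np.concatenate([p, c]))
    r_p = float(np.sum(ranks[: p.size]))
    u = r_p - p.size * (p.size + 1) / 2.0
    return u / (p.size * c.size)


def mann_whitney(
    patient_values: np.ndarray, control_values: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of patients over controls, p).

    The exact null distribution is used when n_p * n_c <= 400 and the
    pooled sample is tie-free; otherwise the normal approximation with
    tie and continuity corrections.
    """
    p, c = _clean_groups(patient_values, control_values)
    pooled = np.concatenate([p, c])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (p.size * c.size <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(p, c, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScreeningResult:
    """Per-feature screening statistics for one test type.

    ``frame`` has one row per feature with columns
    feature, U, p, auc, auc_effective, passes_p, passes_auc.
    """

    frame: pd.DataFrame
    n_patients: int
    n_controls: int
    test_type: str
    p_cut: float = DEFAULT_P_CUT
    auc_cut: float = DEFAULT_AUC_CUT

    @property
    def passing_p(self) -> list[str]:
        """Features clearing the p-value cutoff, most significant first."""
        sub = self.frame[self.frame["passes_p"]]
        return list(sub.sort_values("p")["feature"])

    @property
    def passing_auc(self) -> list[str]:
        """Features clearing the AUC cutoff, strongest first."""
        sub = self.frame[self.frame["passes_auc"]]
        return list(sub.sort_values("auc_effective", ascending=False)["feature"])

    def summary(self) -> str:
        lines = [
            f"Feature screening ({self.test_type}): "
            f"{self.n_patients} patients vs {self.n_controls} controls",
            f"cutoffs: p <= {self.p_cut:g} | effective AUC >= {self.auc_cut:g}",
            f"{len(self.passing_p)} features pass the p cutoff, "
            f"{len(self.passing_auc)} pass the AUC cutoff",
            "-" * 72,
        ]
        shown = self.frame.sort_values("p").head(15)
        lines.append(f"{'feature':<48}{'p':>10}{'AUC':>8}")
        for _, row in shown.iterrows():
            lines.append(
                f"{row['feature'][:47]:<48}{row['p']:>10.2e}{row['auc_effective']:>8.3f}"
            )
        return "\n".join(lines)


def screen(
    table: pd.DataFrame,
    p_cut: float = DEFAULT_P_CUT,
    auc_cut: float = DEFAULT_AUC_CUT,
    feature_names: list[str] | None = None,
) -> ScreeningResult:
    """Screen every feature column of a feature table.

    The table must contain a single test type and both class labels;
    static and dynamic tests are screened separately.  Subjects with a
    NaN in a feature are dropped for that feature only; a feature left
    with an empty group gets NaN statistics and fails both cutoffs.
    """
    test_types = table["test_type"].unique()
    if len(test_types) != 1:
        raise ValueError(
            f"screen expects a single test type, got {sorted(map(str, test_types))}"
        )
    labels = set(table["label"].unique())
    if not {"patient", "control"} <= labels:
        raise ValueError("screening needs both patient and control rows")
    if feature_names is None:
        feature_names = [c for c in table.columns if c not in META_COLUMNS]

    is_patient = (table["label"] == "patient").to_numpy()
    rows = []
    for name in feature_names:
        col = table[name].to_numpy(dtype=float)
        pv, cv = col[is_patient], col[~is_patient]
        try:
            u, p = mann_whitney(pv, cv)
            auc = feature_auc(pv, cv)
        except ValueError:
            u = p = auc = float("nan")
        auc_eff = max(auc, 1.0 - auc) if np.isfinite(auc) else float("nan")
        rows.append(
            {
                "feature": name,
                "U": u,
                "p": p,
                "auc": auc,
                "auc_effective": auc_eff,
                "passes_p": bool(np.isfinite(p) and p <= p_cut),
                "passes_auc": bool(np.isfinite(auc_eff) and auc_eff >= auc_cut),
            }
        )
    return ScreeningResult(
        frame=pd.DataFrame(rows),
        n_patients=int(is_patient.sum()),
        n_controls=int((~is_patient).sum()),
        test_type=str(test_types[0]),
        p_cut=p_cut,
        auc_cut=auc_cut,
    )
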