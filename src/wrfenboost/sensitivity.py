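"""Drug-effectiveness inference and validation statistics.

Two binarisation rules turn sensitivity measurements into effectiveness
labels: the GI50 rule (a drug is effective when its GI50 sits strictly
below the maximum tested concentration, i.e. the concentration difference
GI50 - max_conc is negative) and the active-area rule (mean-centre the
active areas; effective above mean + 0.8 s, ineffective below mean -
0.8 s, excluded in between, with s the sample standard deviation).
Predicted viabilities are scored against those labels with ROC and
precision-recall curves — lower predicted viability means a more effective
drug, so ranking uses the negated prediction — and with a Mann-Whitney
comparison of the two label groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve

logger = logging.getLogger(__name__)

EFFECTIVE = "effective"
INEFFECTIVE = "ineffective"
EXCLUDED = "excluded"


def gi50_label(drug_sens: float, test_max_conc: float) -> str:
    """GI50 binarisation: effective iff GI50 - max tested concentration < 0.

    The boundary Δ = 0 (no inhibition reached, GI50 recorded at the highest
    tested concentration) is labelled ineffective.
    """
    if drug_sens is None or test_max_conc is None or np.isnan(drug_sens) or np.isnan(test_max_conc):
        raise ValueError("gi50_label requires both drug_sens and test_max_conc")
    return EFFECTIVE if drug_sens - test_max_conc < 0 else INEFFECTIVE


def active_area_label(values, band: float = 0.8) -> list:
    """Active-area binarisation around the mean ± band·SD.

    Values are centred by their mean; a record is effective above
    ``band`` sample standard deviations, ineffective below, excluded in
    the middle band.  Zero spread excludes everything with a warning.
    """
    a = np.asarray(values, float)
    if a.size < 2:
        raise ValueError("need at least 2 active-area values")
    mu = a.mean()
    s = a.std(ddof=1)
    if s == 0:
        logger.warning("zero spread in active areas: all records excluded")
        return [EXCLUDED] * a.size
    out = []
    for v in a - mu:
        if v > band * s:
            out.append(EFFECTIVE)
        elif v < -band * s:
            out.append(INEFFECTIVE)
        else:
            out.append(EXCLUDED)
    return out


def min_viability_collapse(records: pd.DataFrame, score_col: str = "predicted_viability",
                           keys=("pert_id", "cell_line")) -> pd.DataFrame:
    """Keep, per (drug, cell line), the record with lowest predicted viability."""
    if records.empty:
        return records.copy()
    idx = records.groupby(list(keys), sort=False)[score_col].idxmin()
    return records.loc[idx].reset_index(drop=True)


def concentration_filter(records: pd.DataFrame, min_dose: float = 10.0,
                         dose_col: str = "dose_um") -> pd.DataFrame:
    """Keep records whose dose is >= ``min_dose`` µM (boundary retained)."""
    return records.loc[records[dose_col] >= min_dose].reset_index(drop=True)


@dataclass
class RocPrResult:
    roc_points: pd.DataFrame  # fpr, tpr
    auroc: float
    pr_points: pd.DataFrame  # recall, precision
    aupr: float
    score_orientation: str = "negated predicted viability (lower viability => effective)"


def roc_pr(labels, predicted_viability) -> RocPrResult:
    """ROC and PR curves for effectiveness vs predicted viability.

    ``labels`` are effectiveness labels or booleans (effective = positive);
    scoring ranks by negated predicted viability.  AUCs are trapezoidal;
    tied scores collapse into one threshold step.
    """
    y = np.asarray([(l == EFFECTIVE or l is True or l == 1) for l in labels], bool)
    score = -np.asarray(predicted_viability, float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to build ROC/PR curves")
    fpr, tpr, _ = roc_curve(y, score)
    auroc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y, score)
    # recall is non-increasing along the curve; integrate in that order so
    # tied-recall points contribute zero-width segments
    aupr = float(-np.trapezoid(precision, recall))
    return RocPrResult(
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        auroc=auroc,
        pr_points=pd.DataFrame({"recall": recall, "precision": precision}),
        aupr=aupr,
    )


def mann_whitney(effective_scores, ineffective_scores, alternative: str = "two-sided"):
    """Mann-Whitney U comparison of two score groups.

    Uses exact enumeration when the combined sample is small (n <= 12) and
    tie-free, the tie-corrected normal approximation otherwise.  Returns
    (U, p) with U the statistic of the first group.
    """
    a = np.asarray(effective_scores, float)
    b = np.asarray(ineffective_scores, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def regression_metrics(observed, predicted) -> tuple[float, float, float]:
    """(Pearson r, R², MSE) of predicted vs observed viability."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    if np.std(obs) == 0:
        raise ValueError("constant observed values: Pearson and R² undefined")
    r = float(stats.pearsonr(obs, pred)[0]) if np.std(pred) > 0 else float("nan")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return r, 1.0 - ss_res / ss_tot, ss_res / obs.size


@dataclass
class EvaluationReport:
    """Regression and effectiveness-classification metrics of one model."""

    pearson: float
    r_squared: float
    mse: float
    auroc: float | None = None
    aupr: float | None = None
    mann_whitney_u: float | None = None
    mann_whitney_p: float | None = None
    label_counts: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "r_squared": self.r_squared,
            "mse": self.mse,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "mann_whitney_u": self.mann_whitney_u,
            "mann_whitney_p": self.mann_whitney_p,
            "label_counts": self.label_counts,
            "notes": self.notes,
        }


def evaluate(observed, predicted, labels=None, mw_alternative: str = "less") -> EvaluationReport:
    """Full report: regression metrics plus, when labels are given,
    ROC/PR AUCs and a Mann-Whitney test that effective drugs have lower
    predicted viability (one-sided by default)."""
    r, r2, mse = regression_metrics(observed, predicted)
    report = EvaluationReport(pearson=r, r_squared=r2, mse=mse)
    if labels is not None:
        labels = list(labels)
        pred = np.asarray(predicted, float)
        keep = [i for i, l in enumerate(labels) if l != EXCLUDED]
        kept_labels = [labels[i] for i in keep]
        kept_pred = pred[keep]
        counts = pd.Series(labels).value_counts().to_dict()
        report.label_counts = {str(k): int(v) for k, v in counts.items()}
        eff = kept_pred[[l == EFFECTIVE for l in kept_labels]]
        ineff = kept_pred[[l == INEFFECTIVE for l in kept_labels]]
        if eff.size and ineff.size:
            rp = roc_pr(kept_labels, kept_pred)
            report.auroc, report.aupr = rp.auroc, rp.aupr
            u, p = mann_whitney(eff, ineff, alternative=mw_alternative)
            report.mann_whitney_u, report.mann_whitney_p = u, p
            report.notes["score_orientation"] = rp.score_orientation
            report.notes["mann_whitney_alternative"] = mw_alternative
    return report
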