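"""Censored evaluation protocol for screening risk scores.

All statistics consume a "records" DataFrame with one row per scored exam:
``patient_id, exam_id, score, event, time_years, age, birads, prior_bc,
biopsy_benign_within_90d`` (plus optional ``risk_j`` columns).

Conventions:

* horizon AUC at ``j`` years: positives are exams followed by a diagnosis
  within ``j`` years; negatives are exams with at least ``j`` event-free
  years of follow-up; exams censored before ``j`` without an event are
  excluded; score ties count 1/2.  Undefined AUCs (no positives or no
  negatives) are reported as ``None``, never imputed.
* windowed AUC (a, b]: drop exams diagnosed within ``a`` years, then take
  the horizon AUC at ``b`` — isolates long-term risk from detection.
* Uno's C: inverse-probability-of-censoring-weighted concordance truncated
  at ``tau``, with the censoring distribution estimated by Kaplan-Meier.
* age-adjusted AUC: placement-value covariate-adjusted ROC with a linear
  location model for the age-conditional control score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# horizon and windowed AUC
# ---------------------------------------------------------------------------

def _horizon_labels(records: pd.DataFrame, j: float):
    event = records["event"].to_numpy(dtype=bool)
    time = records["time_years"].to_numpy(dtype=float)
    pos = event & (time <= j)
    neg = ~pos & (time >= j)
    return pos, neg


def horizon_auc(records: pd.DataFrame, j: float,
                score_col: str = "score") -> float | None:
    """AUC for "diagnosis within j years" under right censoring."""
    from sklearn.metrics import roc_auc_score

    pos, neg = _horizon_labels(records, j)
    keep = pos | neg
    if pos.sum() == 0 or neg.sum() == 0:
        return None
    y = pos[keep].astype(int)
    s = records[score_col].to_numpy(dtype=float)[keep]
    return float(roc_auc_score(y, s))


def windowed_auc(records: pd.DataFrame, a: float, b: float,
                 score_col: str = "score") -> float | None:
    """Long-term AUC: exclude exams diagnosed within ``a`` years, evaluate at ``b``."""
    if not 0 <= a < b:
        raise ValueError("need 0 <= a < b")
    event = records["event"].to_numpy(dtype=bool)
    time = records["time_years"].to_numpy(dtype=float)
    keep = ~(event & (time <= a))
    return horizon_auc(records.loc[keep], b, score_col)


# ---------------------------------------------------------------------------
# Uno's C-index
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    cindex: float
    n_comparable: int
    ipcw: bool          # False = unweighted Harrell fallback


def uno_c_index(records: pd.DataFrame, tau: float = 10.0,
                score_col: str = "score") -> ConcordanceResult:
    """IPCW concordance truncated at ``tau`` (Uno), Kaplan-Meier censoring
    weights; falls back to unweighted Harrell concordance (flagged) when the
    censoring distribution is degenerate."""
    from sksurv.metrics import concordance_index_ipcw
    from sksurv.util import Surv

    event = records["event"].to_numpy(dtype=bool)
    time = records["time_years"].to_numpy(dtype=float)
    score = records[score_col].to_numpy(dtype=float)
    y = Surv.from_arrays(event=event, time=time)
    try:
        c, concordant, discordant, tied_risk, _ = concordance_index_ipcw(
            y, y, score, tau=tau)
        return ConcordanceResult(float(c), int(concordant + discordant + tied_risk),
                                 ipcw=True)
    except (ValueError, ZeroDivisionError):
        c, n = _harrell(event, time, score, tau)
        return ConcordanceResult(c, n, ipcw=False)


def _harrell(event, time, score, tau) -> tuple[float, int]:
    num = den = 0.0
    n_pairs = 0
    n = len(time)
    for i in range(n):
        if not event[i] or time[i] >= tau:
            continue
        for k in range(n):
            if time[k] > time[i]:
                n_pairs += 1
                den += 1
                if score[i] > score[k]:
                    num += 1
                elif score[i] == score[k]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den, n_pairs


# ---------------------------------------------------------------------------
# age-adjusted AUC (placement-value AROC)
# ---------------------------------------------------------------------------

def age_adjusted_auc(records: pd.DataFrame, j: float,
                     score_col: str = "score", min_controls: int = 10) -> float | None:
    """Covariate-adjusted AUC: regress control scores on age (linear location
    model), keep empirical residuals, and average case placement values in
    the age-conditional control distribution.  Reduces exactly to the plain
    AUC when age is constant."""
    pos, neg = _horizon_labels(records, j)
    if pos.sum() == 0:
        return None
    if neg.sum() < min_controls:
        raise ValueError(f"need at least {min_controls} controls, have {int(neg.sum())}")
    s = records[score_col].to_numpy(dtype=float)
    age = records["age"].to_numpy(dtype=float)
    s_ctrl, a_ctrl = s[neg], age[neg]
    s_case, a_case = s[pos], age[pos]
    if np.ptp(a_ctrl) < 1e-12:
        slope, intercept = 0.0, s_ctrl.mean()
    else:
        slope, intercept = np.polyfit(a_ctrl, s_ctrl, 1)
    resid = s_ctrl - (intercept + slope * a_ctrl)
    # predicted control distribution at each case's age: mu(age) + residuals
    mu_case = intercept + slope * a_case
    diff = s_case[:, None] - (mu_case[:, None] + resid[None, :])
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (len(s_case) * len(resid)))


# ---------------------------------------------------------------------------
# DeLong's paired AUC test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _auc_structural(scores: np.ndarray, labels: np.ndarray):
    """AUC plus DeLong structural components V10 (cases), V01 (controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    return auc, v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float]:
    """Two-sided DeLong test for paired AUCs on identical records.

    Returns ``(delta_auc, p_value)`` with ``delta = AUC_A - AUC_B``.
    Identical score vectors give (0, 1).
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must share a shape")
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be 0/1")
    auc_a, v10_a, v01_a = _auc_structural(scores_a, labels)
    auc_b, v10_b, v01_b = _auc_structural(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(delta), float(p)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(statistic, records: pd.DataFrame, n_boot: int = 1000,
                 seed: int = 0, max_undefined_frac: float = 0.2
                 ) -> tuple[float, float]:
    """Patient-level bootstrap 95% percentile interval of ``statistic(df)``.

    ``statistic`` may return None (undefined on a resample); if more than
    ``max_undefined_frac`` of resamples are undefined the interval is refused.
    """
    rng = np.random.default_rng(seed)
    patients = records["patient_id"].unique()
    groups = {p: g for p, g in records.groupby("patient_id")}
    values = []
    undefined = 0
    for _ in range(n_boot):
        draw = rng.choice(patients, size=len(patients), replace=True)
        df = pd.concat([groups[p] for p in draw], ignore_index=True)
        try:
            v = statistic(df)
        except Exception:
            v = None
        if v is None or (isinstance(v, float) and np.isnan(v)):
            undefined += 1
        else:
            values.append(float(v))
    if undefined > max_undefined_frac * n_boot:
        raise ValueError(f"statistic undefined on {undefined}/{n_boot} resamples")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Kaplan-Meier percentile stratification
# ---------------------------------------------------------------------------

PERCENTILE_GROUPS = ((0, 10), (10, 50), (50, 90), (90, 100))


def km_strata(records: pd.DataFrame, horizon: float = 10.0,
              score_col: str = "score") -> dict:
    """Stratify the evaluated population into score-percentile groups
    (0-10, 10-50, 50-90, 90-100) and fit a KM curve per group.

    Ties across a cut are resolved deterministically by (score, patient_id,
    exam_id) order.  Returns per-group counts, % cancers within the group,
    % of all cancers, and the KM cancer-free curve.
    """
    from lifelines import KaplanMeierFitter

    if len(records) < 10:
        raise ValueError("need at least 10 records to stratify")
    df = records.sort_values([score_col, "patient_id", "exam_id"],
                             kind="mergesort").reset_index(drop=True)
    n = len(df)
    cuts = [0, round(0.10 * n), round(0.50 * n), round(0.90 * n), n]
    event = df["event"].to_numpy(dtype=bool)
    time = df["time_years"].to_numpy(dtype=float)
    cancer_within = event & (time <= horizon)
    total_cancers = int(cancer_within.sum())
    out = {"groups": [], "horizon": horizon, "n": n,
           "total_cancers": total_cancers}
    for (lo_pct, hi_pct), lo, hi in zip(PERCENTILE_GROUPS, cuts[:-1], cuts[1:]):
        sel = slice(lo, hi)
        grp_event = event[sel]
        grp_time = np.minimum(time[sel], horizon)
        grp_event = grp_event & (time[sel] <= horizon)
        kmf = KaplanMeierFitter()
        kmf.fit(grp_time, event_observed=grp_event)
        n_grp = hi - lo
        n_cancer = int(cancer_within[sel].sum())
        out["groups"].append({
            "percentile_range": (lo_pct, hi_pct),
            "n": n_grp,
            "n_cancers": n_cancer,
            "pct_cancer_in_group": 100.0 * n_cancer / n_grp if n_grp else float("nan"),
            "pct_of_all_cancers": 100.0 * n_cancer / total_cancers if total_cancers else 0.0,
            "km_times": kmf.survival_function_.index.to_numpy(dtype=float),
            "km_survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        })
    return out


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------

COHORTS = ("screening1", "screening2", "recurrence", "bcsc_eligible")


def cohort_filter(records: pd.DataFrame, which: str) -> pd.DataFrame:
    """Subset records per the named evaluation cohort.

    * ``screening1``: BI-RADS 1-2, or any BI-RADS with a benign biopsy within
      90 days of the exam (normal / biopsy-negative screening group);
    * ``screening2``: BI-RADS 0, 1 or 2 (nothing suspicious reported);
    * ``recurrence``: women with a prior breast-cancer history;
    * ``bcsc_eligible``: no prior history and age 35-74 (classical
      risk-calculator eligibility).
    """
    birads = records["birads"].to_numpy(dtype=int)
    prior = records["prior_bc"].to_numpy(dtype=bool)
    if which == "screening1":
        keep = np.isin(birads, [1, 2]) | records["biopsy_benign_within_90d"].to_numpy(bool)
    elif which == "screening2":
        keep = np.isin(birads, [0, 1, 2])
    elif which == "recurrence":
        keep = prior
    elif which == "bcsc_eligible":
        age = records["age"].to_numpy(dtype=float)
        keep = (~prior) & (age >= 35) & (age <= 74)
    else:
        raise ValueError(f"unknown cohort {which!r}; expected one of {COHORTS}")
    return records.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_km_strata(strata: dict, path) -> None:
    """Kaplan-Meier cancer-free curves per risk-percentile group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g in strata["groups"]:
        lo, hi = g["percentile_range"]
        ax.step(g["km_times"], g["km_survival"], where="post",
                label=f"{lo}-{hi}th pct (n={g['n']})")
    ax.set_xlabel("years since target exam")
    ax.set_ylabel("cancer-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(records: pd.DataFrame, j: float, path,
             score_col: str = "score") -> None:
    """ROC curve for the j-year horizon (censoring-aware label definition)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    pos, neg = _horizon_labels(records, j)
    keep = pos | neg
    fig, ax = plt.subplots(figsize=(4.2, 4))
    if pos.sum() and neg.sum():
        fpr, tpr, _ = roc_curve(pos[keep].astype(int),
                                records[score_col].to_numpy(float)[keep])
        auc = horizon_auc(records, j, score_col)
        ax.plot(fpr, tpr, label=f"{j:g}-year AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

def metrics_report(records: pd.DataFrame, horizons=range(1, 11),
                   tau: float = 10.0, score_col: str = "score") -> dict:
    """AUC_1..AUC_10, Uno's C and record counts for one cohort of records."""
    report: dict = {"n_exams": int(len(records)),
                    "n_patients": int(records["patient_id"].nunique()),
                    "n_events": int(records["event"].sum())}
    aucs = {}
    for j in horizons:
        auc = horizon_auc(records, j, score_col)
        aucs[f"auc_{j}y"] = auc
    report.update(aucs)
    defined = [v for v in aucs.values() if v is not None]
    report["mean_auc_1_10"] = float(np.mean(defined)) if defined else None
    try:
        c = uno_c_index(records, tau=tau, score_col=score_col)
        report["c_index"] = c.cindex
        report["c_index_ipcw"] = c.ipcw
    except ValueError:
        report["c_index"] = None
    return report
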