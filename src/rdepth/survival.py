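"""LASSO-Cox feature selection, risk scoring and risk-group evaluation.

Features are z-scored on the training set and fed to an L1-penalized Cox
proportional-hazards fit; the penalty is chosen by k-fold cross-validated
partial likelihood (Verweij & van Houwelingen). The nonzero-coefficient
features define a continuous risk score

    Risc = sum_g q_g * z_g,

the linear predictor over the selected standardized features, and subjects
are stratified into high-/low-risk groups at the median training Risc.
Evaluation reports the two-sample log-rank test, Harrell's concordance
index of the scores against (time, event), and the hazard ratio between the
two groups from a univariate Cox fit with a Wald 95% CI.

The modelling surface follows the Model / Results convention:
``LassoCoxRiskModel(features, survival).fit()`` returns a
``RiskStratificationResults`` carrying the frozen ``RiskModel`` (scaler,
coefficients, threshold), training diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

__all__ = [
    "SurvivalConfig",
    "RiskModel",
    "LassoCoxRiskModel",
    "RiskStratificationResults",
    "EvaluationReport",
    "fit_lasso_cox",
    "risk_score",
    "stratify",
    "evaluate",
    "cox_partial_loglik",
    "plot_km",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalConfig:
    """Penalty-path and cross-validation settings for the LASSO-Cox fit."""

    n_folds: int = 5
    n_alphas: int = 50
    alpha_min_ratio: float = 0.01
    seed: int = 0


@dataclass
class RiskModel:
    """Frozen artifacts of a fitted LASSO-Cox risk model.

    Holds the selected feature names, their Cox coefficients q_g, the
    training standardization (center/scale) and raw-scale medians used for
    imputation, the stratification threshold on Risc, and the chosen
    penalty. Everything needed to score unseen subjects with no training
    data present.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    train_median: np.ndarray
    threshold: float
    alpha: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.train_median = np.asarray(self.train_median, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def n_selected(self) -> int:
        return len(self.feature_names)

    def to_json(self, path) -> None:
        doc = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "train_median": self.train_median.tolist(),
            "threshold": self.threshold,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            feature_names=list(doc["feature_names"]),
            coefficients=np.asarray(doc["coefficients"]),
            center=np.asarray(doc["center"]),
            scale=np.asarray(doc["scale"]),
            train_median=np.asarray(doc["train_median"]),
            threshold=float(doc["threshold"]),
            alpha=float(doc["alpha"]),
            seed=int(doc.get("seed", 0)),
        )


def cox_partial_loglik(lp: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> float:
    """Cox partial log-likelihood of linear predictors (Breslow ties)."""
    lp = np.asarray(lp, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(-time, kind="stable")
    lp_s, t_s, e_s = lp[order], time[order], event[order]
    # log of the running risk-set sum, numerically stabilized
    m = lp_s.max() if lp_s.size else 0.0
    cum = np.cumsum(np.exp(lp_s - m))
    # risk set of an event at t includes every subject with time >= t;
    # with descending sort, ties require the last index of the tied block
    last_tied = np.searchsorted(-t_s, -t_s, side="right") - 1
    log_denom = np.log(cum[last_tied]) + m
    return float(np.sum(lp_s[e_s] - log_denom[e_s]))


def _drop_degenerate(x: pd.DataFrame) -> pd.DataFrame:
    bad = []
    for c in x.columns:
        col = x[c].to_numpy(float)
        if np.isinf(col).any() or np.isnan(col).all() or \
                np.nanstd(col) == 0:
            bad.append(c)
    if bad:
        warnings.warn(
            f"dropping {len(bad)} constant or non-finite feature(s) before "
            "the penalized fit", stacklevel=3)
        x = x.drop(columns=bad)
    return x


def _feature_matrix(features: pd.DataFrame) -> pd.DataFrame:
    x = features.copy()
    if "subject_id" in x.columns:
        x = x.set_index("subject_id")
    return x.astype(float)


def _aligned(features: pd.DataFrame, survival: pd.DataFrame):
    x = _feature_matrix(features)
    surv = survival.set_index("subject_id").loc[x.index]
    return x, surv["time"].to_numpy(float), surv["event"].to_numpy(int)


class LassoCoxRiskModel:
    """L1-penalized Cox risk model over a feature table.

    Parameters
    ----------
    features : DataFrame
        One row per subject; a ``subject_id`` column (or the index) plus
        numeric feature columns.
    survival : DataFrame
        ``subject_id, time, event`` rows covering every feature subject.
    config : SurvivalConfig
    """

    def __init__(self, features: pd.DataFrame, survival: pd.DataFrame,
                 config: SurvivalConfig = SurvivalConfig()):
        self.features = features
        self.survival = survival
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: SurvivalConfig = SurvivalConfig()):
        """Build from one table carrying time/event plus feature columns."""
        surv = df[["subject_id", "time", "event"]]
        feats = df.drop(columns=["time", "event"])
        return cls(feats, surv, config)

    def fit(self) -> "RiskStratificationResults":
        cfg = self.config
        x, time, event = _aligned(self.features, self.survival)
        if int(event.sum()) < 2:
            raise ValueError("need at least 2 observed events to fit")
        x = _drop_degenerate(x)
        median = x.median(axis=0).to_numpy()
        x = x.fillna(x.median(axis=0))
        center = x.mean(axis=0).to_numpy()
        scale = x.std(axis=0, ddof=1).to_numpy()
        scale[scale == 0] = 1.0
        z = (x.to_numpy(float) - center) / scale
        y = Surv.from_arrays(event=event.astype(bool), time=time)

        path_model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=cfg.n_alphas,
            alpha_min_ratio=cfg.alpha_min_ratio)
        path_model.fit(z, y)
        alphas = np.asarray(path_model.alphas_)

        # Verweij & van Houwelingen cross-validated partial likelihood
        cvpl = np.zeros(len(alphas))
        kf = KFold(n_splits=cfg.n_folds, shuffle=True,
                   random_state=cfg.seed)
        for train_idx, _ in kf.split(z):
            fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
            fold.fit(z[train_idx], y[train_idx])
            coefs = fold.coef_  # (p, n_alphas)
            lp_all = z @ coefs
            lp_tr = z[train_idx] @ coefs
            for a in range(len(alphas)):
                cvpl[a] += (
                    cox_partial_loglik(lp_all[:, a], time, event)
                    - cox_partial_loglik(lp_tr[:, a], time[train_idx],
                                         event[train_idx]))
        best = int(np.argmax(cvpl))
        alpha = float(alphas[best])

        final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha])
        final.fit(z, y)
        coef = final.coef_[:, 0]
        sel = np.flatnonzero(coef != 0)
        names = [x.columns[i] for i in sel]
        scores = z[:, sel] @ coef[sel] if sel.size else np.zeros(len(x))
        threshold = float(np.median(scores))
        model = RiskModel(
            feature_names=names,
            coefficients=coef[sel],
            center=center[sel],
            scale=scale[sel],
            train_median=median[sel],
            threshold=threshold,
            alpha=alpha,
            seed=cfg.seed,
        )
        return RiskStratificationResults(
            model=model,
            train_scores=pd.Series(scores, index=x.index, name="risk_score"),
            cv_partial_loglik=pd.Series(cvpl, index=alphas,
                                        name="cv_partial_loglik"),
            train_time=time,
            train_event=event,
        )


@dataclass
class RiskStratificationResults:
    """Fit results: the frozen risk model plus training diagnostics."""

    model: RiskModel
    train_scores: pd.Series
    cv_partial_loglik: pd.Series
    train_time: np.ndarray
    train_event: np.ndarray

    @property
    def train_groups(self) -> np.ndarray:
        return stratify(self.train_scores.to_numpy(), self.model.threshold)

    def concordance(self) -> float:
        """Harrell's C of training risk scores against observed survival."""
        return float(concordance_index_censored(
            self.train_event.astype(bool), self.train_time,
            self.train_scores.to_numpy())[0])

    def predict(self, features: pd.DataFrame) -> pd.Series:
        x = _feature_matrix(features)
        return pd.Series(risk_score(self.model, x), index=x.index,
                         name="risk_score")

    def summary(self) -> str:
        m = self.model
        lines = [
            "LASSO-Cox risk stratification",
            "=" * 45,
            f"selected features:   {m.n_selected}",
            f"penalty alpha:       {m.alpha:.6g}",
            f"Risc threshold:      {m.threshold:.6g} (training median)",
            f"training C-index:    {self.concordance():.3f}",
            f"events / subjects:   {int(self.train_event.sum())}"
            f" / {len(self.train_event)}",
            "",
            f"{'feature':<42s} {'coef q_g':>10s}",
            "-" * 53,
        ]
        order = np.argsort(-np.abs(m.coefficients))
        for i in order:
            lines.append(f"{m.feature_names[i]:<42s} "
                         f"{m.coefficients[i]:>10.4f}")
        return "\n".join(lines)


def fit_lasso_cox(features: pd.DataFrame, survival: pd.DataFrame,
                  config: SurvivalConfig = SurvivalConfig()) -> RiskModel:
    """Functional wrapper returning just the frozen RiskModel."""
    return LassoCoxRiskModel(features, survival, config).fit().model


def risk_score(model: RiskModel, features: pd.DataFrame) -> np.ndarray:
    """Risc = sum_g q_g * z_g over the model's selected features.

    Missing columns or NaN cells are imputed with the training median (a
    warning is logged); an empty model scores every subject 0.
    """
    x = _feature_matrix(features)
    if model.n_selected == 0:
        return np.zeros(len(x))
    cols = np.empty((len(x), model.n_selected))
    for g, name in enumerate(model.feature_names):
        if name not in x.columns:
            logger.warning("feature %r missing; imputing training median",
                           name)
            cols[:, g] = model.train_median[g]
            continue
        col = x[name].to_numpy(float)
        if np.isnan(col).any():
            logger.warning("imputing %d missing values in feature %r",
                           int(np.isnan(col).sum()), name)
            col = np.where(np.isnan(col), model.train_median[g], col)
        cols[:, g] = col
    z = (cols - model.center) / model.scale
    return z @ model.coefficients


def stratify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """'high' iff Risc > threshold, else 'low' (ties are low-risk)."""
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("risk scores must be finite")
    return np.where(scores > threshold, "high", "low")


@dataclass
class EvaluationReport:
    """Log-rank, C-index and hazard-ratio summary of a scored cohort."""

    c_index: float
    logrank_stat: float | None = None
    logrank_p: float | None = None
    hazard_ratio: float | None = None
    hr_ci_low: float | None = None
    hr_ci_high: float | None = None
    n_high: int = 0
    n_low: int = 0
    groups: pd.Series | None = field(default=None, repr=False)

    def to_json(self, path) -> None:
        doc = {k: v for k, v in self.__dict__.items() if k != "groups"}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def evaluate(groups: np.ndarray, scores: np.ndarray,
             survival: pd.DataFrame) -> EvaluationReport:
    """Evaluate stratified groups and continuous scores on a cohort.

    The C-index uses Harrell's censoring-aware pair definition (higher
    score = higher risk = shorter survival; tied scores count 0.5;
    censored-censored pairs are excluded). With a single nonempty group the
    log-rank test and hazard ratio are skipped with a warning.
    """
    groups = np.asarray(groups)
    scores = np.asarray(scores, float)
    time = survival["time"].to_numpy(float)
    event = survival["event"].to_numpy(int)
    cidx = float(concordance_index_censored(event.astype(bool), time,
                                            scores)[0])
    high = groups == "high"
    n_high, n_low = int(high.sum()), int((~high).sum())
    report = EvaluationReport(c_index=cidx, n_high=n_high, n_low=n_low,
                              groups=pd.Series(groups))
    if n_high == 0 or n_low == 0:
        warnings.warn("single risk group; skipping log-rank and hazard "
                      "ratio", stacklevel=2)
        return report
    lr = logrank_test(time[high], time[~high],
                      event_observed_A=event[high],
                      event_observed_B=event[~high])
    report.logrank_stat = float(lr.test_statistic)
    report.logrank_p = float(lr.p_value)
    df = pd.DataFrame({"time": time, "event": event,
                       "high_risk": high.astype(int)})
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        report.hazard_ratio = float(np.exp(cph.params_["high_risk"]))
        ci = cph.confidence_intervals_.loc["high_risk"]
        report.hr_ci_low = float(np.exp(ci.iloc[0]))
        report.hr_ci_high = float(np.exp(ci.iloc[1]))
    except Exception as exc:  # pragma: no cover - convergence pathologies
        warnings.warn(f"hazard-ratio fit failed: {exc}", stacklevel=2)
    return report


def plot_km(groups: np.ndarray, survival: pd.DataFrame, path=None):
    """Kaplan-Meier curves of the two risk groups (optionally saved)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = np.asarray(groups)
    time = survival["time"].to_numpy(float)
    event = survival["event"].to_numpy(int)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name in ("low", "high"):
        sel = groups == name
        if not sel.any():
            continue
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=f"{name}-risk (n={sel.sum()})")
        km.plot_survival_function(ax=ax)
    ax.set_xlabel("overall survival (days)")
    ax.set_ylabel("estimated survival probability")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
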