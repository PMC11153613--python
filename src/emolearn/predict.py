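"""Logistic prediction of follow-up treatment resistance from five baseline
measures: right-amygdala (decision), left-pallidum and mPFC (feedback)
activity in the emotional condition, ACC Glu/tCr, and the overall proportion
of ideal choices.

The model is a plain in-sample maximum-likelihood logistic regression (no
regularisation, no cross-validation): fit quality is summarised by
Nagelkerke's pseudo-R² and the apparent confusion matrix at a 0.5
probability threshold. Features are z-scored before the headline fit so the
coefficients are comparable across the heterogeneous units; an unscaled fit
is emitted alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

FEATURES = ["amygdala_beta", "pallidum_beta", "mpfc_beta", "glu_tcr", "ideal_choice_overall"]


@dataclass
class LogisticFit:
    coef: pd.Series  # includes const
    pvalues: pd.Series
    llf: float  # model log-likelihood L1
    llnull: float  # intercept-only log-likelihood L0
    n: int
    converged: bool
    separation: bool
    scaled: bool
    fitted_prob: np.ndarray = field(repr=False, default=None)


@dataclass
class PredictionReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity_pct: int
    specificity_pct: int
    accuracy_pct: int
    sensitivity: float
    specificity: float
    accuracy: float
    nagelkerke_r2: float
    coefficients: dict
    separation: bool

    def __post_init__(self) -> None:
        n = self.tp + self.fn + self.tn + self.fp
        assert n > 0
        # internal consistency of the headline percentages with the counts
        if self.tp + self.fn > 0:
            assert self.sensitivity_pct == round(100.0 * self.tp / (self.tp + self.fn))
        if self.tn + self.fp > 0:
            assert self.specificity_pct == round(100.0 * self.tn / (self.tn + self.fp))
        assert self.accuracy_pct == round(100.0 * (self.tp + self.tn) / n)


def build_features(
    roi: pd.DataFrame,
    metabolites: pd.DataFrame,
    fits: pd.DataFrame,
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the five visit-A predictors plus the visit-C outcome label.

    ROI betas come from the emotional condition (amygdala: decision phase;
    pallidum and mPFC: feedback); glutamate from QC-passed visit-A Glu/tCr;
    behaviour is the overall proportion of ideal choices pooled over
    conditions at visit A. Complete cases only.
    """
    from .mrs import qc_filter

    a = roi.loc[(roi["visit"] == "A") & (roi["condition"] == "emotional")]
    wide = a.pivot_table(index="participant_id", columns="region", values="beta")
    wide = wide.rename(
        columns={"right_amygdala": "amygdala_beta", "left_pallidum": "pallidum_beta",
                 "mpfc": "mpfc_beta"}
    )
    glu_ok, _ = qc_filter(metabolites.loc[metabolites["metabolite"] == "Glu"])
    glu = (
        glu_ok.loc[glu_ok["visit"] == "A"]
        .set_index("participant_id")["value"]
        .rename("glu_tcr")
    )
    behav = (
        fits.loc[fits["visit"] == "A"]
        .groupby("participant_id")["prop_ideal"]
        .mean()
        .rename("ideal_choice_overall")
    )
    lab = labels.loc[labels["label"].isin(["resistant", "responsive"])].set_index(
        "participant_id"
    )["label"]
    out = wide.join([glu, behav]).join(lab.rename("label"), how="inner")
    out["outcome"] = (out["label"] == "resistant").astype(int)
    return out.dropna(subset=FEATURES).reset_index()


def fit_logistic(features: pd.DataFrame, scale: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic fit of resistance on the five predictors.

    Features are z-scored when ``scale`` is true. Complete or quasi-complete
    separation is detected and flagged; the fit is still reported (with the
    usual caveat that coefficients diverge).
    """
    y = features["outcome"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one case in each outcome class")
    X = features[FEATURES].astype(float).copy()
    if scale:
        X = (X - X.mean()) / X.std(ddof=0)
    X = sm.add_constant(X)

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # IRLS blow-up under exact separation
            separation = True
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
        separation = separation or any(
            issubclass(w.category, (PerfectSeparationWarning, RuntimeWarning)) for w in caught
        )
    fitted = np.asarray(res.predict(X))
    if np.all((fitted > 1 - 1e-9) == (y == 1)) and np.all((fitted < 1e-9) == (y == 0)):
        separation = True
    return LogisticFit(
        coef=res.params,
        pvalues=res.pvalues,
        llf=float(res.llf),
        llnull=float(res.llnull),
        n=len(y),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        scaled=scale,
        fitted_prob=fitted,
    )


def nagelkerke_r2(l0: float, l1: float, n: int) -> float:
    """Nagelkerke's rescaled Cox-Snell pseudo-R².

    R²_CS = 1 - exp(2 (L0 - L1) / n); Nagelkerke = R²_CS / (1 - exp(2 L0 / n)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if l1 < l0 - 1e-9:
        raise ValueError("model log-likelihood cannot be below the null's for nested MLE")
    r2_cs = 1.0 - np.exp(2.0 * (l0 - min(l1, 0.0)) / n)
    denom = 1.0 - np.exp(2.0 * l0 / n)
    if denom <= 0:
        return 0.0
    return float(min(r2_cs / denom, 1.0))


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity/specificity/accuracy (exact fractions and whole percents)."""
    out: dict = {"tp": tp, "fn": fn, "tn": tn, "fp": fp}
    pos, neg = tp + fn, tn + fp
    out["sensitivity"] = tp / pos if pos else np.nan
    out["specificity"] = tn / neg if neg else np.nan
    out["accuracy"] = (tp + tn) / (pos + neg)
    for k in ("sensitivity", "specificity", "accuracy"):
        out[f"{k}_pct"] = int(round(100.0 * out[k])) if np.isfinite(out[k]) else None
    return out


def cross_validated_metrics(
    features: pd.DataFrame, k: int = 5, threshold: float = 0.5, seed: int = 0,
    scale: bool = True,
) -> dict:
    """Stratified k-fold out-of-sample confusion metrics (optional mode).

    Off the default path — the headline report is the apparent in-sample
    classification — but useful to gauge optimism with 5 predictors and few
    events. Folds are stratified by outcome; scaling parameters are
    re-estimated inside each training fold.
    """
    rng = np.random.default_rng(seed)
    y = features["outcome"].to_numpy(dtype=int)
    idx_pos = rng.permutation(np.flatnonzero(y == 1))
    idx_neg = rng.permutation(np.flatnonzero(y == 0))
    folds: list[np.ndarray] = [
        np.concatenate([idx_pos[i::k], idx_neg[i::k]]) for i in range(k)
    ]
    tp = fn = tn = fp = 0
    for test_idx in folds:
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        train, test = features.loc[~mask], features.loc[mask]
        if train["outcome"].nunique() < 2:
            continue
        fit = fit_logistic(train, scale=scale)
        X_test = test[FEATURES].astype(float)
        if scale:
            X_train = train[FEATURES].astype(float)
            X_test = (X_test - X_train.mean()) / X_train.std(ddof=0)
        X_test = sm.add_constant(X_test, has_constant="add")
        prob = expit(X_test.to_numpy() @ fit.coef.to_numpy())
        pred = (prob >= threshold).astype(int)
        yt = test["outcome"].to_numpy(dtype=int)
        tp += int(np.sum((pred == 1) & (yt == 1)))
        fn += int(np.sum((pred == 0) & (yt == 1)))
        tn += int(np.sum((pred == 0) & (yt == 0)))
        fp += int(np.sum((pred == 1) & (yt == 0)))
    return metrics_from_confusion(tp, fn, tn, fp)


def classify_and_report(
    fit: LogisticFit, features: pd.DataFrame, threshold: float = 0.5
) -> PredictionReport:
    """Apparent (in-sample) classification report at the given threshold."""
    y = features["outcome"].to_numpy(dtype=int)
    pred = (fit.fitted_prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    m = metrics_from_confusion(tp, fn, tn, fp)
    return PredictionReport(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity_pct=m["sensitivity_pct"],
        specificity_pct=m["specificity_pct"],
        accuracy_pct=m["accuracy_pct"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
        nagelkerke_r2=nagelkerke_r2(fit.llnull, fit.llf, fit.n),
        coefficients={
            name: {
                "beta": float(fit.coef[name]),
                # Wald p is undefined (NaN) under separation; report as None
                "p": float(fit.pvalues[name]) if np.isfinite(fit.pvalues[name]) else None,
            }
            for name in fit.coef.index
        },
        separation=fit.separation,
    )
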