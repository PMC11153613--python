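"""MRS glutamate statistics and the synthetic metabolite / ROI-beta generator.

Glutamate is expressed as a ratio to total creatine (Glu/tCr) from a single
anterior-cingulate voxel. Estimates enter analysis only if they pass the
spectral quality gate: CRLB < 20 %, signal-to-noise ratio > 10 and linewidth
FWHM < 0.1 ppm (all strict inequalities). Statistics are the group x visit
mixed ANOVA on Glu/tCr, a paired t-test on the tCr reference across visits,
Spearman correlations between regional activity and Glu/tCr, and a Fisher
r-to-z comparison of two independent correlation coefficients.

The Fisher comparison is applied to Spearman coefficients with the ordinary
Pearson-style variance 1/(n-3); this is an approximation for rank
correlations but is the convention the statistic reproduces here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import mixed_anova

CRLB_MAX_PCT = 20.0
SNR_MIN = 10.0
FWHM_MAX_PPM = 0.1

QC_COLUMNS = ("crlb_pct", "snr", "fwhm")

REGIONS = ("right_amygdala", "left_pallidum", "mpfc")
#: task phase feeding each region's headline parameter estimate
REGION_PHASE = {"right_amygdala": "decision", "left_pallidum": "feedback", "mpfc": "feedback"}


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z1: float
    z2: float
    Z: float
    p: float


def qc_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split metabolite records into QC-passing rows and an exclusion log.

    A row is kept iff crlb_pct < 20 and snr > 10 and fwhm < 0.1 (strict).
    Rows with any missing QC field are excluded as incomplete. The exclusion
    log lists every failing criterion per excluded row.
    """
    missing = [c for c in QC_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records lack QC columns: {missing}")
    reasons = []
    for _, row in records.iterrows():
        fails = []
        if any(pd.isna(row[c]) for c in QC_COLUMNS):
            fails.append("incomplete QC fields")
        else:
            if not row["crlb_pct"] < CRLB_MAX_PCT:
                fails.append(f"CRLB {row['crlb_pct']:.3g}% >= {CRLB_MAX_PCT:g}%")
            if not row["snr"] > SNR_MIN:
                fails.append(f"SNR {row['snr']:.3g} <= {SNR_MIN:g}")
            if not row["fwhm"] < FWHM_MAX_PPM:
                fails.append(f"FWHM {row['fwhm']:.3g} >= {FWHM_MAX_PPM:g} ppm")
        reasons.append("; ".join(fails))
    reasons_arr = np.array(reasons, dtype=object)
    keep = reasons_arr == ""
    included = records.loc[keep].copy()
    excluded = records.loc[~keep].copy()
    excluded["exclusion_reason"] = reasons_arr[~keep]
    return included, excluded


def glutamate_anova(records: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Group x visit mixed ANOVA on QC-passed Glu/tCr values."""
    glu = records.loc[records["metabolite"] == "Glu"].merge(labels, on="participant_id")
    glu = glu.loc[glu["label"].isin(["resistant", "responsive"])]
    return mixed_anova(
        glu, dv="value", subject="participant_id", between="label", within=["visit"]
    )


def creatine_stability(records: pd.DataFrame) -> dict:
    """Paired t-test of tCr between visits A and C (reference stability)."""
    tcr = records.loc[records["metabolite"] == "tCr"]
    wide = tcr.pivot_table(index="participant_id", columns="visit", values="value")
    paired = wide.dropna(subset=["A", "C"])
    n_dropped = len(wide) - len(paired)
    t, p = stats.ttest_rel(paired["A"], paired["C"])
    return {"t": float(t), "df": len(paired) - 1, "p": float(p), "n": len(paired),
            "n_dropped": n_dropped}


def spearman_corr(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rank correlation (midranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "n": len(x), "p": np.nan, "defined": False}
    r, p = stats.spearmanr(x, y)
    return {"r": float(r), "n": len(x), "p": float(p), "defined": True}


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent correlations via the Fisher r-to-z transform.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-tailed p
    from the standard normal.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError(f"|r| must be < 1, got {r}")
    if n1 < 4 or n2 < 4:
        raise ValueError("both groups need n >= 4")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    Z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(Z))
    return CorrelationComparison(r1, n1, r2, n2, float(z1), float(z2), float(Z), float(p))


# --------------------------------------------------------------------------
# synthetic metabolite + ROI generator


@dataclass(frozen=True)
class EffectConfig:
    """Cell means for the synthetic ROI betas and the glutamate coupling.

    ``roi_means[(group, region)] = (visit_A_mean, visit_C_mean)`` in arbitrary
    beta units (SD ``roi_sd``); ``coupling_rho`` is the latent Pearson
    correlation between visit-C mPFC betas and Glu/tCr in the responsive
    group (the resistant group is uncoupled). QC fields are drawn so roughly
    95 % of records pass the quality gate.
    """

    roi_means: dict = field(
        default_factory=lambda: {
            ("resistant", "right_amygdala"): (-0.5, 0.4),
            ("responsive", "right_amygdala"): (0.4, 0.35),
            ("resistant", "left_pallidum"): (-0.5, 0.45),
            ("responsive", "left_pallidum"): (0.45, -0.1),
            ("resistant", "mpfc"): (0.35, -0.5),
            ("responsive", "mpfc"): (0.0, 0.55),
        }
    )
    roi_sd: float = 0.6
    glu_mean: float = 1.20  # Glu/tCr, dimensionless
    glu_sd: float = 0.12
    tcr_mean: float = 1.0  # institutional units
    tcr_sd: float = 0.07
    coupling_rho: float = -0.48  # latent Pearson; Spearman ~= -0.46 under normality
    qc_pass_target: float = 0.95


def generate_mrs_roi_data(
    labels: pd.DataFrame,
    config: EffectConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic metabolite and ROI-beta tables emulating the study pattern.

    Resistant agents: blunted amygdala/pallidum activity at baseline rising
    by follow-up and mPFC falling; responsive: mPFC rising. Visit-C mPFC
    betas and Glu/tCr are negatively coupled in the responsive group only.
    Deterministic for a fixed seed; returns ``(metabolites, roi_betas)``.
    """
    config = EffectConfig() if config is None else config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    rho = config.coupling_rho
    if not abs(rho) < 1:
        raise ValueError("coupling_rho must satisfy |rho| < 1")

    met_rows, roi_rows = [], []
    for _, part in labels.sort_values("participant_id").iterrows():
        pid, group = part["participant_id"], part["label"]
        if group not in ("resistant", "responsive"):
            continue
        z_glu = {"A": rng.standard_normal(), "C": rng.standard_normal()}
        for visit in ("A", "C"):
            glu = config.glu_mean + config.glu_sd * z_glu[visit]
            tcr = rng.normal(config.tcr_mean, config.tcr_sd)
            for metab, value in (("Glu", glu), ("tCr", tcr)):
                # ~95% joint pass rate: each criterion fails ~1.7% of the time
                met_rows.append(
                    {
                        "participant_id": pid,
                        "visit": visit,
                        "metabolite": metab,
                        "value": max(value, 1e-3),
                        "crlb_pct": float(np.clip(rng.normal(8, 5.6), 0.5, 60)),
                        "snr": float(np.clip(rng.normal(22, 5.6), 2, 60)),
                        "fwhm": float(np.clip(rng.normal(0.055, 0.021), 0.01, 0.3)),
                    }
                )
            for region in REGIONS:
                mean_a, mean_c = config.roi_means[(group, region)]
                mean = mean_a if visit == "A" else mean_c
                if region == "mpfc" and visit == "C" and group == "responsive":
                    z = rho * z_glu["C"] + np.sqrt(1 - rho**2) * rng.standard_normal()
                else:
                    z = rng.standard_normal()
                roi_rows.append(
                    {
                        "participant_id": pid,
                        "visit": visit,
                        "region": region,
                        "phase": REGION_PHASE[region],
                        "condition": "emotional",
                        "beta": mean + config.roi_sd * z,
                    }
                )
    return pd.DataFrame(met_rows), pd.DataFrame(roi_rows)


def mpfc_glutamate_coupling(
    metabolites: pd.DataFrame, roi: pd.DataFrame, labels: pd.DataFrame, visit: str = "C"
) -> dict:
    """Per-group visit-C Spearman correlations (mPFC beta vs Glu/tCr) and
    their Fisher comparison. Uses QC-passed glutamate rows only."""
    glu_ok, _ = qc_filter(metabolites.loc[metabolites["metabolite"] == "Glu"])
    glu = glu_ok.loc[glu_ok["visit"] == visit, ["participant_id", "value"]]
    mpfc = roi.loc[(roi["region"] == "mpfc") & (roi["visit"] == visit),
                   ["participant_id", "beta"]]
    merged = glu.merge(mpfc, on="participant_id").merge(labels, on="participant_id")
    out: dict = {}
    for group, df in merged.groupby("label"):
        if group in ("resistant", "responsive"):
            out[group] = spearman_corr(df["beta"].to_numpy(), df["value"].to_numpy())
    if {"resistant", "responsive"} <= out.keys():
        resp, res = out["responsive"], out["resistant"]
        out["comparison"] = fisher_z_compare(resp["r"], resp["n"], res["r"], res["n"])
    return out
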