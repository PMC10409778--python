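"""Adjusted odds ratios for documentation and positive use.

Two settings mirror the study design: (1) documentation — patients with
any cannabis mention vs. patients with none; (2) positive use — positive
patients vs. a comparator (all non-positive patients by default, or
documented-negatives only). Covariates are sex (reference male), race
(reference white), and the Social Vulnerability Index expressed per 0.01
units. The default estimator is a fixed-effects logistic GLM — one row
per patient leaves nothing to cluster on — with a random-intercept
variant available when a cluster column (e.g. clinic site) is supplied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import PatientStatus
from .screening import SentenceHit

logger = logging.getLogger(__name__)

__all__ = [
    "DisparityResult",
    "build_design",
    "fit_disparity_model",
    "exclude_medical_cannabis",
]

SETTINGS = ("documentation", "positive_use")

# Covariate columns reported as contrasts, with their reference levels.
CONTRASTS = {
    "female": "male",
    "race_asian": "white",
    "race_black": "white",
    "race_hispanic": "white",
    "race_other": "white",
    "svi_per_001": "per 0.01 SVI",
}


class DisparityError(ValueError):
    pass


@dataclass(frozen=True)
class DisparityResult:
    setting: str
    covariate: str
    aOR: float
    ci_low: float
    ci_high: float
    p_value: float
    reference_level: str
    flagged: bool = False  # separation / unstable fit


def build_design(
    patients: list[object],
    statuses: list[PatientStatus],
    setting: str,
    positive_comparator: str = "all_others",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Outcome vector and covariate matrix for one disparity setting.

    documentation: outcome 1 iff status != undocumented, over all patients.
    positive_use: outcome 1 iff positive; comparator is every non-positive
    patient ("all_others") or documented negatives only
    ("documented_negative").

    Unknown sex and unavailable race get their own indicator columns so
    those patients stay in the model without contaminating the reported
    contrasts; rows missing SVI are dropped (count logged).
    """
    if setting not in SETTINGS:
        raise DisparityError(f"setting must be one of {SETTINGS}, got {setting!r}")
    status_by_pid = {s.patient_id: s.status for s in statuses}
    rows = []
    n_missing_svi = 0
    for p in patients:
        st = status_by_pid.get(p.patient_id, "undocumented")
        if setting == "documentation":
            y = int(st != "undocumented")
        else:
            if positive_comparator == "documented_negative" and st == "undocumented":
                continue
            y = int(st == "positive")
        if p.svi is None:
            n_missing_svi += 1
            continue
        rows.append(
            {
                "patient_id": p.patient_id,
                "y": y,
                "female": int(p.sex == "female"),
                "sex_unknown": int(p.sex == "unknown"),
                "race_asian": int(p.race == "asian"),
                "race_black": int(p.race == "black"),
                "race_hispanic": int(p.race == "hispanic"),
                "race_other": int(p.race == "other"),
                "race_unavailable": int(p.race == "unavailable"),
                "svi_per_001": p.svi * 100.0,
            }
        )
    if n_missing_svi:
        logger.info("build_design: dropped %d patients with missing SVI", n_missing_svi)
    if not rows:
        raise DisparityError("no usable patients in design")
    df = pd.DataFrame(rows)
    y = df.pop("y").to_numpy()
    if y.min() == y.max():
        raise DisparityError("outcome has a single class; model not identifiable")
    return y, df


def fit_disparity_model(
    y: np.ndarray,
    design: pd.DataFrame,
    method: str = "glm_logistic",
    setting: str = "documentation",
    cluster: pd.Series | None = None,
) -> list[DisparityResult]:
    """Fit the logistic model and report exponentiated contrasts.

    Wald 95% CIs and p-values per covariate. Zero-variance covariates are
    dropped with a warning. ``glmm_random_intercept`` adds a cluster
    random intercept (variational Bayes fit) when ``cluster`` is given.
    Suspiciously large coefficients (|log aOR| > 15) are flagged as
    probable separation.
    """
    X = design.drop(columns=["patient_id"], errors="ignore").astype(float)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping zero-variance covariates: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    Xc = sm.add_constant(X, has_constant="add")

    if method == "glm_logistic":
        fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
        params, bse, pvalues = fit.params, fit.bse, fit.pvalues
    elif method == "glmm_random_intercept":
        if cluster is None:
            raise DisparityError("glmm_random_intercept requires a cluster column")
        model = sm.BinomialBayesMixedGLM(
            y, Xc, exog_vc=pd.get_dummies(cluster).to_numpy(dtype=float),
            ident=np.zeros(cluster.nunique(), dtype=int),
        )
        res = model.fit_vb()
        k = Xc.shape[1]
        params = pd.Series(res.fe_mean[:k], index=Xc.columns)
        bse = pd.Series(res.fe_sd[:k], index=Xc.columns)
        z = params / bse
        from scipy import stats as _st

        pvalues = pd.Series(2 * _st.norm.sf(np.abs(z)), index=Xc.columns)
    else:
        raise DisparityError(f"unknown method {method!r}")

    zcrit = 1.959963984540054
    results = []
    for cov, ref in CONTRASTS.items():
        if cov not in params.index:
            continue
        beta, se = float(params[cov]), float(bse[cov])
        with np.errstate(over="ignore"):  # separated fits: CI is honestly inf
            ci_low = float(np.exp(beta - zcrit * se))
            ci_high = float(np.exp(beta + zcrit * se))
        results.append(
            DisparityResult(
                setting=setting,
                covariate=cov,
                aOR=float(np.exp(beta)),
                ci_low=ci_low,
                ci_high=ci_high,
                p_value=float(pvalues[cov]),
                reference_level=ref,
                flagged=abs(beta) > 15,
            )
        )
    return results


_MEDICAL_ONLY = {
    "marinol",
    "dronabinol",
    "epidiolex",
    "syndros",
    "cesamet",
    "cannabidiol",
}

_RX_CUES = ("rx", "prescri", "mg", "tab", "refill", "dose")


def exclude_medical_cannabis(
    statuses: list[PatientStatus],
    positive_labels_by_patient: dict[str, list[tuple[SentenceHit, object]]],
    lexicon=None,
) -> list[PatientStatus]:
    """Sensitivity reassignment: drop prescription-cannabinoid-only positives.

    A patient whose every positive sentence mentions only prescription
    cannabinoid terms in a prescription context (RX, mg, tab, ...) is
    reassigned to negative_documented for the re-fit. Patients with any
    recreational-term positive evidence are untouched.

    ``positive_labels_by_patient`` maps patient_id -> list of
    (SentenceHit, UseLabel) pairs for their positive sentences.
    """
    medical = set(lexicon.medical_terms) & _MEDICAL_ONLY if lexicon else _MEDICAL_ONLY
    out = []
    for s in statuses:
        if s.status != "positive":
            out.append(s)
            continue
        evidence = positive_labels_by_patient.get(s.patient_id, [])
        def is_medical(pair):
            hit, _ = pair
            terms = {h.canonical_seed for h in hit.hits}
            low = hit.sentence_text.lower()
            return bool(terms) and terms <= medical and any(c in low for c in _RX_CUES)
        if evidence and all(is_medical(pair) for pair in evidence):
            out.append(PatientStatus(s.patient_id, "negative_documented"))
        else:
            out.append(s)
    return out
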