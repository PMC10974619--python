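"""Linear mixed models over error records: factor attribution, ANOVA
tables, anthropometric comparison and Nakagawa–Schielzeth R².

The unit of analysis is one :class:`~limbaug.metrics.ErrorRecord` (one
subject x model x movement x landmark, or x joint x axis x side).  Models
carry the experimental factors as fixed effects with sum-to-zero contrasts
and a random intercept per subject:

* position errors: model + movement + landmark + model:movement
  + model:landmark;
* angle errors: model + movement + joint + axis + side + model:movement
  + model:joint + model:axis + joint:axis + model:joint:axis.

Variance components are estimated by REML (through statsmodels' MixedLM);
the ANOVA table reports Type-III sums of squares computed on the
GLS-whitened regression implied by the estimated compound-symmetry
covariance.  The anthropometric comparison is a likelihood-ratio test
between ML refits with and without sex/height/weight as fixed covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf

from .datamodel import AnthropometricProfile
from .metrics import ErrorRecord, records_to_frame

__all__ = [
    "ErrorMixedModel",
    "ErrorLmmResults",
    "compare_anthropometrics",
    "r2_nakagawa",
    "simulate_position_records",
]

_POSITION_TERMS = (
    "C(model, Sum)",
    "C(movement, Sum)",
    "C(landmark, Sum)",
    "C(model, Sum):C(movement, Sum)",
    "C(model, Sum):C(landmark, Sum)",
)

_ANGLE_TERMS = (
    "C(model, Sum)",
    "C(movement, Sum)",
    "C(joint, Sum)",
    "C(axis, Sum)",
    "C(side, Sum)",
    "C(model, Sum):C(movement, Sum)",
    "C(model, Sum):C(joint, Sum)",
    "C(model, Sum):C(axis, Sum)",
    "C(joint, Sum):C(axis, Sum)",
    "C(model, Sum):C(joint, Sum):C(axis, Sum)",
)

_ANTHRO_TERMS = ("sex", "height", "weight")

#: Human-readable row labels for the ANOVA tables.
_TERM_LABELS = {
    "C(model, Sum)": "Model",
    "C(movement, Sum)": "Movement",
    "C(landmark, Sum)": "Anatomical landmark",
    "C(joint, Sum)": "Joint",
    "C(axis, Sum)": "Axis",
    "C(side, Sum)": "Side",
    "C(model, Sum):C(movement, Sum)": "Model:Movement",
    "C(model, Sum):C(landmark, Sum)": "Model:Anatomical landmark",
    "C(model, Sum):C(joint, Sum)": "Model:Joint",
    "C(model, Sum):C(axis, Sum)": "Model:Axis",
    "C(joint, Sum):C(axis, Sum)": "Joint:Axis",
    "C(model, Sum):C(joint, Sum):C(axis, Sum)": "Model:Joint:Axis",
    "sex": "Sex",
    "height": "Height",
    "weight": "Weight",
}


def _profiles_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    rows = []
    for p in (profiles.values() if isinstance(profiles, dict)
              else profiles):
        rows.append({"subject": p.subject_id, "sex": float(p.sex_code),
                     "height": p.height, "weight": p.weight})
    return pd.DataFrame(rows)


class ErrorMixedModel:
    """Mixed model for error records with a per-subject random intercept.

    Parameters
    ----------
    records : sequence of ErrorRecord
        Homogeneous in ``kind``.
    kind : {"position", "angle"}
    include_anthropometrics : bool
        Add sex, height and weight as fixed covariates (requires
        ``profiles``).
    profiles : dict, sequence or DataFrame, optional
        Subject anthropometrics, keyed/identified by subject id.
    """

    def __init__(self, records: Sequence[ErrorRecord], kind: str,
                 include_anthropometrics: bool = False,
                 profiles=None):
        records = list(records)
        if not records:
            raise ValueError("no records")
        kinds = {r.kind for r in records}
        if kinds != {kind}:
            raise ValueError(
                f"records of kind {sorted(kinds)} do not match {kind!r}")
        if kind not in ("position", "angle"):
            raise ValueError(f"unknown kind {kind!r}")
        df = records_to_frame(records)
        if df["subject"].nunique() < 2:
            raise ValueError(
                "at least 2 subjects required to identify the subject "
                "random effect")
        factors = (("model", "movement", "landmark") if kind == "position"
                   else ("model", "movement", "joint", "axis", "side"))
        for factor in factors:
            if df[factor].nunique() < 2:
                raise ValueError(
                    f"factor {factor!r} has no variation (aliased); "
                    "cannot be estimated")
        if include_anthropometrics:
            if profiles is None:
                raise ValueError(
                    "include_anthropometrics requires subject profiles")
            prof = _profiles_frame(profiles)
            missing = set(df["subject"]) - set(prof["subject"])
            if missing:
                raise ValueError(
                    f"profiles missing for subjects {sorted(missing)}")
            df = df.merge(prof, on="subject", how="left")
        self.data = df
        self.kind = kind
        self.include_anthropometrics = include_anthropometrics
        terms = _POSITION_TERMS if kind == "position" else _ANGLE_TERMS
        if include_anthropometrics:
            terms = _ANTHRO_TERMS + terms
        self.terms = terms
        self.formula = "value ~ " + " + ".join(terms)

    @classmethod
    def from_records(cls, records, kind, **kwargs) -> "ErrorMixedModel":
        return cls(records, kind, **kwargs)

    def fit(self, reml: bool = True, **fit_kwargs) -> "ErrorLmmResults":
        model = smf.mixedlm(self.formula, self.data, groups="subject")
        # A subject variance near zero puts the optimum on the parameter
        # boundary, where individual optimizers can stall or (worse)
        # report convergence at a spurious point.  Try several and keep
        # the fit with the best restricted/full likelihood.
        best = None
        for method in (None, "powell", "cg"):
            kwargs = dict(fit_kwargs)
            if method is not None:
                kwargs["method"] = method
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(reml=reml, **kwargs)
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if not np.isfinite(res.llf):
                continue
            if best is None or res.llf > best.llf + 1e-8:
                best = res
            if best.converged and method is None:
                break
        if best is None:
            raise RuntimeError("mixed-model fit failed for every optimizer")
        return ErrorLmmResults(model=self, _sm=best, reml=reml)


@dataclass
class ErrorLmmResults:
    """Fitted error mixed model.

    Exposes fixed effects with standard errors, the two variance
    components, a Type-III ANOVA table and the marginal/conditional R².
    """

    model: ErrorMixedModel
    _sm: object
    reml: bool = True

    # -- parameter access --------------------------------------------------
    @property
    def fe_params(self) -> pd.Series:
        return self._sm.fe_params

    @property
    def bse_fe(self) -> pd.Series:
        return self._sm.bse_fe

    @property
    def subject_var(self) -> float:
        return float(np.asarray(self._sm.cov_re)[0, 0])

    @property
    def resid_var(self) -> float:
        return float(self._sm.scale)

    @property
    def llf(self) -> float:
        return float(self._sm.llf)

    @property
    def converged(self) -> bool:
        return bool(self._sm.converged)

    # -- R² ----------------------------------------------------------------
    def r2(self) -> Tuple[float, float]:
        return r2_nakagawa(self)

    @property
    def r2_marginal(self) -> float:
        return self.r2()[0]

    @property
    def r2_conditional(self) -> float:
        return self.r2()[1]

    def fixed_effect_variance(self) -> float:
        """Population variance of the fixed-effect linear predictor."""
        X = patsy.dmatrix(self.model.formula.split("~", 1)[1],
                          self.model.data, return_type="dataframe")
        eta = X.to_numpy() @ self.fe_params.to_numpy()
        return float(np.var(eta))

    # -- ANOVA ---------------------------------------------------------------
    def anova(self) -> pd.DataFrame:
        """Type-III ANOVA table (factor, SS, MS, DoF).

        Sums of squares are computed on the GLS-whitened regression: each
        subject's block is decorrelated with the estimated compound-symmetry
        covariance (scaled so the whitened residual variance equals the
        residual variance), then each term's SS is the increase in residual
        sum of squares when its columns are dropped from the full
        sum-to-zero design.
        """
        rhs = self.model.formula.split("~", 1)[1]
        X = patsy.dmatrix(rhs, self.model.data, return_type="dataframe")
        design_info = X.design_info
        Xm = X.to_numpy()
        y = self.model.data["value"].to_numpy(dtype=float)
        groups = self.model.data["subject"].to_numpy()

        sigma2 = self.resid_var
        tau2 = self.subject_var
        Xw = np.empty_like(Xm)
        yw = np.empty_like(y)
        for g in np.unique(groups):
            idx = np.nonzero(groups == g)[0]
            n = len(idx)
            theta = 1.0 - np.sqrt(sigma2 / (sigma2 + n * tau2))
            block_y = y[idx]
            block_X = Xm[idx]
            yw[idx] = block_y - theta * block_y.mean()
            Xw[idx] = block_X - theta * block_X.mean(axis=0)

        beta, rss_full = _ols_rss(Xw, yw)
        rows = []
        for term_name in design_info.term_names:
            if term_name == "Intercept":
                continue
            sl = design_info.term_name_slices[term_name]
            keep = np.ones(Xm.shape[1], dtype=bool)
            keep[sl] = False
            _, rss_red = _ols_rss(Xw[:, keep], yw)
            ss = max(rss_red - rss_full, 0.0)
            dof = sl.stop - sl.start
            rows.append({
                "factor": _TERM_LABELS.get(term_name, term_name),
                "SS": ss, "MS": ss / dof, "DoF": dof,
            })
        table = pd.DataFrame(rows).set_index("factor")
        table.attrs["residual_SS"] = float(rss_full)
        table.attrs["residual_DoF"] = int(len(y) - Xm.shape[1])
        return table

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        anova = self.anova()
        r2m, r2c = self.r2()
        lines = [
            f"Mixed model for {self.model.kind} errors",
            "=" * 56,
            f"observations: {len(self.model.data)}   subjects: "
            f"{self.model.data['subject'].nunique()}",
            f"estimation: {'REML' if self.reml else 'ML'}   "
            f"log-likelihood: {self.llf:.2f}",
            f"subject SD: {np.sqrt(self.subject_var):.4f}   "
            f"residual SD: {np.sqrt(self.resid_var):.4f}",
            "",
            anova.round(2).to_string(),
            "",
            f"Conditional R2 = {r2c:.3f}, Marginal R2 = {r2m:.3f}",
        ]
        return "\n".join(lines)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def r2_nakagawa(fit: ErrorLmmResults) -> Tuple[float, float]:
    """Marginal and conditional R² (Nakagawa–Schielzeth).

    marginal = var(fixed) / (var(fixed) + var(subject) + var(residual));
    conditional adds the subject variance to the numerator.
    """
    vf = fit.fixed_effect_variance()
    vu = fit.subject_var
    ve = fit.resid_var
    total = vf + vu + ve
    return vf / total, (vf + vu) / total


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(full: ErrorLmmResults,
                          reduced: ErrorLmmResults) -> LrtResult:
    """Chi-square likelihood-ratio test between nested ML fits."""
    for fit in (full, reduced):
        if fit.reml:
            raise ValueError(
                "likelihood-ratio comparison of fixed effects requires "
                "ML fits (reml=False)")
        if not np.isfinite(fit.llf):
            raise ValueError("fit did not converge (non-finite likelihood)")
        if not fit.converged:
            # boundary fits (zero subject variance) routinely trip the
            # optimizer flag while the likelihood itself is fine
            warnings.warn("comparing a fit whose optimizer flag reports "
                          "non-convergence", RuntimeWarning, stacklevel=2)
    df = len(full.fe_params) - len(reduced.fe_params)
    if df < 0:
        raise ValueError("models are not nested (full has fewer terms)")
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    if df == 0:
        warnings.warn("identical fixed-effect structures compared "
                      "(0 degrees of freedom); p = 1", RuntimeWarning,
                      stacklevel=2)
        return LrtResult(statistic=stat, df=0, pvalue=1.0)
    return LrtResult(statistic=stat, df=df,
                     pvalue=float(stats.chi2.sf(stat, df)))


def compare_anthropometrics(records: Sequence[ErrorRecord], kind: str,
                            profiles, method: str = "f") -> float:
    """P-value for whether sex/height/weight influence the errors.

    Refits the factor-only and factor-plus-anthropometrics models by full
    maximum likelihood and compares them with a likelihood-ratio test
    (3 degrees of freedom).

    ``method="f"`` (default) maps the likelihood-ratio statistic to an
    F reference with ``n_subjects - 4`` denominator degrees of freedom.
    The anthropometric covariates are constant within subject, so the
    effective sample for them is the number of subjects (tens, not
    thousands); against the chi-squared reference the test would be
    markedly anticonservative.  The transform inverts the exact relation
    between the likelihood ratio and the F statistic in the
    between-subject regression stratum.  ``method="chisq"`` gives the
    uncorrected large-sample test.
    """
    reduced = ErrorMixedModel(records, kind).fit(reml=False)
    full = ErrorMixedModel(records, kind, include_anthropometrics=True,
                           profiles=profiles).fit(reml=False)
    lrt = likelihood_ratio_test(full, reduced)
    if lrt.df == 0 or method == "chisq":
        return lrt.pvalue
    if method != "f":
        raise ValueError(f"unknown method {method!r}")
    m = full.model.data["subject"].nunique()
    q = lrt.df
    df2 = m - q - 1
    if df2 < 1:
        return lrt.pvalue
    F = (np.exp(lrt.statistic / m) - 1.0) * df2 / q
    return float(stats.f.sf(F, q, df2))


# ---------------------------------------------------------------------------
# simulation helpers (parameter-recovery experiments)
# ---------------------------------------------------------------------------

def simulate_position_records(
    n_subjects: int = 14,
    models: Sequence[str] = ("mlp", "lstm", "transformer"),
    movements: Sequence[str] = ("A-pose", "gait", "running", "squats",
                                "j-jacks", "jump", "f-jump", "t-jump"),
    landmarks: Sequence[str] = None,
    grand_mean: float = 1.5,
    model_effects: Optional[Dict[str, float]] = None,
    landmark_effects: Optional[Dict[str, float]] = None,
    subject_sd: float = 0.2,
    resid_sd: float = 0.3,
    anthro_height_slope: float = 0.0,
    seed: int = 0,
) -> Tuple[List[ErrorRecord], List[AnthropometricProfile]]:
    """Synthetic position error records with known generating structure.

    value = grand_mean + model effect + landmark effect + subject intercept
    + optional height effect + Gaussian residual, truncated at zero (the
    truncation is negligible at the default scales).  Effects are
    sum-to-zero over the supplied levels.
    """
    from .datamodel import LANDMARK_TARGET_ORDER

    rng = np.random.default_rng(seed)
    if landmarks is None:
        landmarks = LANDMARK_TARGET_ORDER

    def _centered(effects, levels):
        eff = {lv: 0.0 for lv in levels}
        if effects:
            eff.update(effects)
        shift = np.mean(list(eff.values()))
        return {lv: v - shift for lv, v in eff.items()}

    m_eff = _centered(model_effects, models)
    l_eff = _centered(landmark_effects, landmarks)

    records = []
    profiles = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        height = rng.normal(1.70, 0.12)
        height = float(np.clip(height, 1.45, 2.0))
        profiles.append(AnthropometricProfile(
            subject_id=sid, sex_code=int(rng.random() < 0.5),
            height=height, weight=float(np.clip(
                73.6 + 80 * (height - 1.70) + rng.normal(0, 10), 40, 150)),
        ))
        u = rng.normal(0.0, subject_sd)
        for model in models:
            for movement in movements:
                for lm in landmarks:
                    mu = (grand_mean + m_eff[model] + l_eff[lm] + u
                          + anthro_height_slope * (height - 1.70))
                    v = mu + rng.normal(0.0, resid_sd)
                    records.append(ErrorRecord(
                        subject_id=sid, model=model, movement=movement,
                        kind="position", landmark=lm,
                        value=max(v, 0.0)))
    return records, profiles
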