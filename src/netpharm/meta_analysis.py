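"""Evidence synthesis across clinical studies: MD / RR / OR pooling.

Per-study effects use standard large-sample formulas: mean difference
MD = mean_e - mean_c with variance sd_e^2/n_e + sd_c^2/n_c; log risk ratio
ln[(e_e/t_e)/(e_c/t_c)] with variance 1/e_e - 1/t_e + 1/e_c - 1/t_c; log odds
ratio analogously. A study with a zero cell gets the 0.5 continuity
correction applied to all four cells; a binary study with zero events in both
arms carries no information about the ratio and is excluded with a warning.

Heterogeneity is measured by Cochran's Q = sum w_i (theta_i - pooled)^2 with
fixed-effect inverse-variance weights w_i = 1/v_i, its chi-square p-value at
df = k - 1, and I^2 = max(0, (Q - df)/Q) * 100. Pooling is inverse-variance:
the fixed-effect model uses w_i directly; the random-effects model uses the
DerSimonian-Laird moment estimator

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))

and re-weights by w*_i = 1/(v_i + tau^2). Under the conventional
model-selection rule, I^2 >= 50% selects random effects, otherwise fixed.
Confidence intervals are normal-approximation pooled +/- 1.96 se; ratio
effects are exponentiated in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph_io import StudyTable

logger = logging.getLogger("netpharm")

__all__ = ["MetaResult", "study_effect", "pool_fixed", "pool_random", "run_meta", "forest_table"]

Z95 = 1.96
EFFECT_TYPES = ("MD", "logRR", "logOR")
I2_THRESHOLD = 50.0


@dataclass
class MetaResult:
    effect_type: str
    pooled: float
    se: float
    ci95: tuple[float, float]
    Q: float
    df: int
    p_het: float
    i2: float
    tau2: float
    model: str
    per_study: pd.DataFrame

    def __post_init__(self):
        lo, hi = self.ci95
        if abs(lo - (self.pooled - Z95 * self.se)) > 1e-9 or abs(hi - (self.pooled + Z95 * self.se)) > 1e-9:
            raise ValueError("ci95 inconsistent with pooled +/- 1.96 se")
        if not 0.0 <= self.i2 <= 100.0:
            raise ValueError("i2 must be in [0, 100]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")

    @property
    def is_ratio(self) -> bool:
        return self.effect_type in ("logRR", "logOR")

    def report(self) -> dict:
        """Pooled effect on the reporting scale (ratios exponentiated)."""
        f = np.exp if self.is_ratio else (lambda x: x)
        return {
            "effect_type": self.effect_type,
            "pooled": float(f(self.pooled)),
            "ci95": [float(f(self.ci95[0])), float(f(self.ci95[1]))],
            "Q": self.Q,
            "df": self.df,
            "p_het": self.p_het,
            "i2": self.i2,
            "tau2": self.tau2,
            "model": self.model,
            "n_studies": int(self.df + 1),
        }


def study_effect(record: pd.Series | dict, effect_type: str) -> tuple[float, float]:
    """Per-study (effect, variance) on the analysis (log for ratios) scale.

    Binary records with a zero cell are continuity-corrected by adding 0.5 to
    all four cells. Raises if both arms have zero events (no estimable
    ratio); callers exclude such studies.
    """
    if effect_type not in EFFECT_TYPES:
        raise ValueError(f"effect_type must be one of {EFFECT_TYPES}")
    r = dict(record)
    if effect_type == "MD":
        effect = r["mean_e"] - r["mean_c"]
        var = r["sd_e"] ** 2 / r["n_e"] + r["sd_c"] ** 2 / r["n_c"]
        return float(effect), float(var)

    ee, te, ec, tc = (float(r[k]) for k in ("events_e", "total_e", "events_c", "total_c"))
    if ee == 0 and ec == 0:
        raise ValueError(f"study {r.get('study', '?')!r}: zero events in both arms")
    zeros = ee == 0 or ec == 0 or ee == te or ec == tc
    if zeros:
        # 0.5 added to all four cells of the affected study
        ee, ec, te, tc = ee + 0.5, ec + 0.5, te + 0.5, tc + 0.5
    if effect_type == "logRR":
        effect = np.log((ee / te) / (ec / tc))
        var = 1.0 / ee - 1.0 / te + 1.0 / ec - 1.0 / tc
    else:  # logOR
        ne, nc = te - ee, tc - ec
        if ne <= 0 or nc <= 0:
            raise ValueError(f"study {r.get('study', '?')!r}: no non-events in an arm")
        effect = np.log((ee / ne) / (ec / nc))
        var = 1.0 / ee + 1.0 / ne + 1.0 / ec + 1.0 / nc
    return float(effect), float(var)


def _heterogeneity(effects: np.ndarray, variances: np.ndarray) -> tuple[float, int, float, float]:
    w = 1.0 / variances
    pooled = float((w * effects).sum() / w.sum())
    q = float((w * (effects - pooled) ** 2).sum())
    df = len(effects) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, i2, pooled


def _result(
    effects: np.ndarray,
    variances: np.ndarray,
    weights: np.ndarray,
    effect_type: str,
    model: str,
    tau2: float,
    labels: list[str],
) -> MetaResult:
    pooled = float((weights * effects).sum() / weights.sum())
    se = float(weights.sum() ** -0.5)
    q, df, i2, _ = _heterogeneity(effects, variances)
    p_het = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    per_study = pd.DataFrame(
        {
            "study": labels,
            "effect": effects,
            "variance": variances,
            "weight_pct": 100.0 * weights / weights.sum(),
        }
    )
    return MetaResult(
        effect_type=effect_type,
        pooled=pooled,
        se=se,
        ci95=(pooled - Z95 * se, pooled + Z95 * se),
        Q=q,
        df=df,
        p_het=p_het,
        i2=i2,
        tau2=tau2,
        model=model,
        per_study=per_study,
    )


def _check(effects, variances) -> tuple[np.ndarray, np.ndarray]:
    effects = np.asarray(effects, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if len(effects) < 2:
        raise ValueError("pooling requires at least 2 studies")
    if (variances <= 0).any():
        raise ValueError("all study variances must be > 0")
    return effects, variances


def pool_fixed(effects, variances, effect_type: str = "MD", labels=None) -> MetaResult:
    """Inverse-variance fixed-effect pooling."""
    effects, variances = _check(effects, variances)
    labels = list(labels) if labels is not None else [f"study{i}" for i in range(len(effects))]
    w = 1.0 / variances
    return _result(effects, variances, w, effect_type, "fixed", 0.0, labels)


def dl_tau2(effects, variances) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    effects, variances = _check(effects, variances)
    w = 1.0 / variances
    q, df, _, _ = _heterogeneity(effects, variances)
    denom = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (q - df) / denom) if denom > 0 else 0.0


def pool_random(effects, variances, effect_type: str = "MD", labels=None) -> MetaResult:
    """DerSimonian-Laird random-effects pooling (reduces to fixed when Q <= df)."""
    effects, variances = _check(effects, variances)
    labels = list(labels) if labels is not None else [f"study{i}" for i in range(len(effects))]
    tau2 = dl_tau2(effects, variances)
    w_star = 1.0 / (variances + tau2)
    return _result(effects, variances, w_star, effect_type, "random", tau2, labels)


def run_meta(
    table: StudyTable,
    effect_type: str | None = None,
    model: str = "auto",
    i2_threshold: float = I2_THRESHOLD,
) -> MetaResult:
    """Pool a study table; model='auto' applies the I^2 >= threshold rule.

    effect_type defaults to MD for continuous tables and logRR for binary
    ones. Binary studies with zero events in both arms are excluded with a
    warning before pooling.
    """
    if model not in ("auto", "fixed", "random"):
        raise ValueError("model must be auto, fixed or random")
    if effect_type is None:
        effect_type = "MD" if table.kind == "continuous" else "logRR"
    if (effect_type == "MD") != (table.kind == "continuous"):
        raise ValueError(f"effect type {effect_type} incompatible with {table.kind} table")

    effects, variances, labels = [], [], []
    for _, row in table.records.iterrows():
        try:
            eff, var = study_effect(row, effect_type)
        except ValueError as exc:
            logger.warning("excluded: %s", exc)
            continue
        effects.append(eff)
        variances.append(var)
        labels.append(row["study"])

    fixed = pool_fixed(effects, variances, effect_type, labels)
    if model == "fixed":
        return fixed
    if model == "random" or fixed.i2 >= i2_threshold:
        return pool_random(effects, variances, effect_type, labels)
    return fixed


def forest_table(result: MetaResult) -> pd.DataFrame:
    """Per-study effects with 95% CIs and weights, plus the pooled row."""
    f = np.exp if result.is_ratio else (lambda x: x)
    df = result.per_study.copy()
    se = np.sqrt(df["variance"])
    out = pd.DataFrame(
        {
            "study": df["study"],
            "effect": f(df["effect"]),
            "ci_low": f(df["effect"] - Z95 * se),
            "ci_high": f(df["effect"] + Z95 * se),
            "weight_pct": df["weight_pct"],
        }
    )
    pooled_row = pd.DataFrame(
        {
            "study": [f"pooled ({result.model})"],
            "effect": [f(result.pooled)],
            "ci_low": [f(result.ci95[0])],
            "ci_high": [f(result.ci95[1])],
            "weight_pct": [100.0],
        }
    )
    return pd.concat([out, pooled_row], ignore_index=True)
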