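"""Agreement validation of automated vs gold-standard PESI scores.

The validation mirrors how an EHR-embedded score calculator is judged
against blinded chart abstraction: exact-score accuracy with an exact
(Clopper-Pearson) binomial confidence interval, agreement on the
five-level risk class and on the binary low/high-risk band, Cohen's
kappa for chance-corrected class agreement, univariable logistic-
regression odds ratios for predictors of agreement, Bland-Altman limits
of agreement on the paired totals, and a per-component error table with
a homogeneity test across component error proportions.

The statsmodels-style entry point is :class:`AgreementStudy`::

    report = AgreementStudy(records).fit()
    print(report.summary())

``evaluate`` is the equivalent functional form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .cohort_sim import ERROR_COMPONENTS, AgreementRecord, records_from_dataframe

__all__ = [
    "exact_binomial_ci",
    "cohen_kappa",
    "logistic_or",
    "bland_altman",
    "evaluate",
    "KappaResult",
    "OddsRatioResult",
    "BlandAltmanResult",
    "AgreementReport",
    "AgreementStudy",
]


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Clopper-Pearson exact two-sided confidence interval for k/n.

    The interval inverts the exact binomial test via beta quantiles:
    lo = BetaInv(alpha/2; k, n-k+1) (0 when k = 0) and
    hi = BetaInv(1-alpha/2; k+1, n-k) (1 when k = n). It always contains
    k/n and is conservative (coverage >= the nominal level).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n]; got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    ci = st.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


class KappaResult(NamedTuple):
    kappa: float
    ci_lo: float
    ci_hi: float
    se: float


def cohen_kappa(a: Sequence, b: Sequence, level: float = 0.95) -> KappaResult:
    """Cohen's kappa between two raters with a large-sample Wald CI.

    kappa = (p_o - p_e) / (1 - p_e), expected agreement p_e from the
    product of marginal label frequencies; SE is the standard
    large-sample approximation sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    When both raters use a single shared label p_e = 1 and kappa is
    undefined; NaNs are returned.
    """
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("label vectors must be non-empty")
    n = len(a)
    labels = sorted(set(a) | set(b), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    p_o = float(np.trace(table)) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if math.isclose(p_e, 1.0):
        return KappaResult(math.nan, math.nan, math.nan, math.nan)
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(max(p_o * (1.0 - p_o), 0.0) / n) / (1.0 - p_e)
    z = st.norm.ppf(0.5 + level / 2)
    return KappaResult(kappa, kappa - z * se, kappa + z * se, se)


class OddsRatioResult(NamedTuple):
    predictor: str
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p_value: float
    estimable: bool
    message: str


def logistic_or(
    outcome: Sequence[bool],
    predictor: Sequence[bool],
    level: float = 0.95,
    name: str = "predictor",
) -> OddsRatioResult:
    """Univariable logistic regression of a binary outcome on a binary
    predictor: OR = exp(slope), Wald CI and p-value.

    For a single binary predictor the maximum-likelihood OR equals the
    2x2 cross-product ratio ad/bc. Separation — an empty cell of the
    2x2 table — makes the OR non-estimable; it is reported as such with
    a diagnostic rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"outcome and predictor differ in length: {len(y)} vs {len(x)}")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    if min(a, b, c, d) == 0:
        return OddsRatioResult(
            name,
            math.nan,
            math.nan,
            math.nan,
            math.nan,
            False,
            f"non-estimable: empty 2x2 cell (a={a}, b={b}, c={c}, d={d})",
        )
    model = sm.Logit(y, sm.add_constant(x))
    fit = model.fit(disp=0, method="newton", maxiter=50, tol=1e-10)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = st.norm.ppf(0.5 + level / 2)
    return OddsRatioResult(
        name,
        math.exp(beta),
        math.exp(beta - z * se),
        math.exp(beta + z * se),
        float(fit.pvalues[1]),
        True,
        "",
    )


class BlandAltmanResult(NamedTuple):
    mean_diff: float
    sd_diff: float
    loa_lo: float
    loa_hi: float
    #: per-point (mean of pair, difference a - b) series for plotting
    points: Tuple[Tuple[float, float], ...]


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement summary for paired measurements.

    mean_diff = mean(a - b); limits of agreement mean_diff +/- 1.96 x
    SD(a - b) (sample SD). The per-point (mean, difference) series is
    returned for plotting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired series differ in length: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    points = tuple((float(m), float(d)) for m, d in zip((a + b) / 2.0, diff))
    return BlandAltmanResult(
        mean_diff, sd_diff, mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff, points
    )


# ---------------------------------------------------------------------------
# Full report

_PREDICTOR_FIELDS = {
    "low_risk": lambda r: r.ppesi_low_risk,
    "first_visit": lambda r: r.first_visit,
    "acute_pe": lambda r: r.acute_pe_on_ct,
}


@dataclass
class AgreementReport:
    """Full validation output; every field is computed from the records.

    Proportions use the cohort size as denominator. ``odds_ratios`` are
    separate univariable fits of exact agreement on each predictor
    (``low_risk`` refers to the gold-standard band). ``homogeneity_p``
    is a chi-square test of homogeneity across the per-component error
    proportions; ``anova_p`` is a one-way ANOVA over the same binary
    indicators, kept for fidelity to reporting conventions that treat
    them as measurements.
    """

    n: int
    ci_level: float
    exact_match_k: int
    exact_match_prop: float
    exact_match_ci: Tuple[float, float]
    class_agreement_k: int
    class_agreement_prop: float
    binary_agreement_k: int
    binary_agreement_prop: float
    discordant_epesi_low: int
    discordant_epesi_high: int
    kappa: KappaResult
    odds_ratios: List[OddsRatioResult]
    bland_altman: BlandAltmanResult
    component_errors: Dict[str, Tuple[int, float]]
    homogeneity_p: float
    anova_p: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "ci_level": self.ci_level,
            "exact_match_k": self.exact_match_k,
            "exact_match_prop": self.exact_match_prop,
            "exact_match_ci": list(self.exact_match_ci),
            "class_agreement_k": self.class_agreement_k,
            "class_agreement_prop": self.class_agreement_prop,
            "binary_agreement_k": self.binary_agreement_k,
            "binary_agreement_prop": self.binary_agreement_prop,
            "discordant_epesi_low": self.discordant_epesi_low,
            "discordant_epesi_high": self.discordant_epesi_high,
            "kappa": list(self.kappa),
            "odds_ratios": [list(o) for o in self.odds_ratios],
            "bland_altman": {
                "mean_diff": self.bland_altman.mean_diff,
                "sd_diff": self.bland_altman.sd_diff,
                "loa_lo": self.bland_altman.loa_lo,
                "loa_hi": self.bland_altman.loa_hi,
                "points": [list(p) for p in self.bland_altman.points],
            },
            "component_errors": {k: list(v) for k, v in self.component_errors.items()},
            "homogeneity_p": self.homogeneity_p,
            "anova_p": self.anova_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        ba = d["bland_altman"]
        return cls(
            n=d["n"],
            ci_level=d["ci_level"],
            exact_match_k=d["exact_match_k"],
            exact_match_prop=d["exact_match_prop"],
            exact_match_ci=tuple(d["exact_match_ci"]),
            class_agreement_k=d["class_agreement_k"],
            class_agreement_prop=d["class_agreement_prop"],
            binary_agreement_k=d["binary_agreement_k"],
            binary_agreement_prop=d["binary_agreement_prop"],
            discordant_epesi_low=d["discordant_epesi_low"],
            discordant_epesi_high=d["discordant_epesi_high"],
            kappa=KappaResult(*d["kappa"]),
            odds_ratios=[OddsRatioResult(*o) for o in d["odds_ratios"]],
            bland_altman=BlandAltmanResult(
                ba["mean_diff"],
                ba["sd_diff"],
                ba["loa_lo"],
                ba["loa_hi"],
                tuple(tuple(p) for p in ba["points"]),
            ),
            component_errors={k: tuple(v) for k, v in d["component_errors"].items()},
            homogeneity_p=d["homogeneity_p"],
            anova_p=d["anova_p"],
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "AgreementReport":
        return cls.from_dict(json.loads(s))

    def summary(self) -> str:
        lines = [
            "Automated vs gold-standard PESI agreement",
            "=" * 57,
            f"patients                         {self.n}",
            (
                f"exact score match                {self.exact_match_k}/{self.n}"
                f" = {100 * self.exact_match_prop:.1f}%"
                f"  ({100 * self.ci_level:.0f}% CI {100 * self.exact_match_ci[0]:.1f}"
                f"-{100 * self.exact_match_ci[1]:.1f}%)"
            ),
            (
                f"risk-class agreement (I-V)       {self.class_agreement_k}/{self.n}"
                f" = {100 * self.class_agreement_prop:.1f}%"
            ),
            (
                f"low/high-risk agreement          {self.binary_agreement_k}/{self.n}"
                f" = {100 * self.binary_agreement_prop:.1f}%"
            ),
            (
                f"discordant band: automated low   {self.discordant_epesi_low}"
                f", automated high {self.discordant_epesi_high}"
            ),
            (
                f"Cohen kappa (class)              {self.kappa.kappa:.3f}"
                f"  ({100 * self.ci_level:.0f}% CI {self.kappa.ci_lo:.3f}-{self.kappa.ci_hi:.3f})"
            ),
            (
                f"Bland-Altman: mean diff {self.bland_altman.mean_diff:+.2f}, "
                f"LoA [{self.bland_altman.loa_lo:.2f}, {self.bland_altman.loa_hi:.2f}]"
            ),
            "-" * 57,
            "odds of exact agreement (univariable logistic):",
        ]
        for o in self.odds_ratios:
            if o.estimable:
                lines.append(
                    f"  {o.predictor:<22} OR {o.odds_ratio:6.2f}"
                    f"  CI {o.ci_lo:.2f}-{o.ci_hi:.2f}  p={o.p_value:.3g}"
                )
            else:
                lines.append(f"  {o.predictor:<22} {o.message}")
        lines.append("-" * 57)
        lines.append("component errors (denominator = cohort):")
        for comp, (k, prop) in self.component_errors.items():
            lines.append(f"  {comp:<22} {k:4d}  ({100 * prop:.1f}%)")
        lines.append(
            f"homogeneity across components    chi2 p={self.homogeneity_p:.3g}"
            f"  (ANOVA p={self.anova_p:.3g})"
        )
        return "\n".join(lines)


def evaluate(
    records: Sequence[AgreementRecord],
    predictors: Sequence[str] = ("low_risk", "first_visit"),
    level: float = 0.95,
) -> AgreementReport:
    """Assemble the full :class:`AgreementReport` from paired records.

    Raises on empty input and on a violation of the nesting invariant
    (an exact score match implies a class match implies a band match).
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    n = len(records)
    for r in records:
        if r.exact_match and not r.class_match:
            raise ValueError(f"{r.patient_id}: exact match without class match")
        if r.class_match and not r.binary_match:
            raise ValueError(f"{r.patient_id}: class match without band match")

    exact_k = sum(r.exact_match for r in records)
    class_k = sum(r.class_match for r in records)
    binary_k = sum(r.binary_match for r in records)

    kappa = cohen_kappa([r.epesi_class for r in records], [r.ppesi_class for r in records], level)

    outcome = [r.exact_match for r in records]
    ors: List[OddsRatioResult] = []
    for pname in predictors:
        if pname not in _PREDICTOR_FIELDS:
            raise KeyError(
                f"unknown predictor {pname!r}; expected one of {sorted(_PREDICTOR_FIELDS)}"
            )
        getter = _PREDICTOR_FIELDS[pname]
        ors.append(logistic_or(outcome, [getter(r) for r in records], level, name=pname))

    ba = bland_altman(
        [float(r.epesi_total) for r in records], [float(r.ppesi_total) for r in records]
    )

    counts = {c: sum(c in r.error_components for r in records) for c in ERROR_COMPONENTS}
    component_errors = {c: (k, k / n) for c, k in counts.items()}
    if sum(counts.values()) == 0:
        homogeneity_p = math.nan
        anova_p = math.nan
    else:
        table = np.array([[k for k in counts.values()], [n - k for k in counts.values()]])
        keep = table.sum(axis=0) > 0
        homogeneity_p = float(st.chi2_contingency(table[:, keep])[1])
        indicators = [
            np.array([1.0 if c in r.error_components else 0.0 for r in records])
            for c in ERROR_COMPONENTS
        ]
        anova_p = float(st.f_oneway(*indicators)[1])

    return AgreementReport(
        n=n,
        ci_level=level,
        exact_match_k=exact_k,
        exact_match_prop=exact_k / n,
        exact_match_ci=exact_binomial_ci(exact_k, n, level),
        class_agreement_k=class_k,
        class_agreement_prop=class_k / n,
        binary_agreement_k=binary_k,
        binary_agreement_prop=binary_k / n,
        discordant_epesi_low=sum(not r.binary_match and r.epesi_low_risk for r in records),
        discordant_epesi_high=sum(not r.binary_match and not r.epesi_low_risk for r in records),
        kappa=kappa,
        odds_ratios=ors,
        bland_altman=ba,
        component_errors=component_errors,
        homogeneity_p=homogeneity_p,
        anova_p=anova_p,
    )


class AgreementStudy:
    """Model-style facade over :func:`evaluate`.

    Built from a list of :class:`AgreementRecord` or (via
    :meth:`from_dataframe`) a records table; :meth:`fit` returns the
    :class:`AgreementReport` results object.
    """

    def __init__(self, records: Sequence[AgreementRecord]):
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AgreementStudy":
        return cls(records_from_dataframe(df))

    def fit(
        self,
        predictors: Sequence[str] = ("low_risk", "first_visit"),
        level: float = 0.95,
    ) -> AgreementReport:
        return evaluate(self.records, predictors=predictors, level=level)
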